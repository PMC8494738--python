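"""Cross-species epigenome conservation against sequence-conservation strata.

The genome is cut into fixed 200-bp segments, each given the mean of a
per-base conservation score track (PhyloP/GERP-like) and ranked into 50
equally sized sets from fastest-changing (set 0) to most conserved (set 49).
Chromatin-state regions are lifted between assemblies through an orthology
map (paired aligned intervals with a sequence-identity weight, 0.65 identity
threshold by default), and each lifted region's epi-conservation rate is the
fraction of it covered by the same state in the target species.  Curves of
mean rate per conservation set, and gene sets stratified by cross-species
expression divergence, summarize the coupling between sequence and
epigenome conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneTable, GenomeAssembly, Segmentation
from .intervals import flatten, overlap_bases

__all__ = [
    "segment_scores",
    "quantile_sets",
    "OrthologyMap",
    "lift_regions",
    "epi_conservation_rate",
    "conservation_curve",
    "pooled_conservation_curve",
    "expression_conservation_sets",
    "mean_rate_around_tss",
]


def segment_scores(
    score_track: pd.DataFrame,
    assembly: GenomeAssembly,
    segment: int = 200,
) -> pd.DataFrame:
    """Mean conservation score per fixed-size genome segment.

    ``score_track`` is bedGraph-like (chrom, start, end, score).  Each
    segment's score is the arithmetic mean over its covered bases; segments
    with no coverage are dropped (their count is recorded in
    ``attrs['n_uncovered']``).
    """
    if score_track.empty:
        raise ValueError("empty score track")
    rows = []
    n_uncovered = 0
    for chrom, length in assembly.chromosomes:
        n_seg = -(-length // segment)
        wsum = np.zeros(n_seg)
        cov = np.zeros(n_seg, dtype=np.int64)
        sub = score_track[score_track["chrom"] == chrom]
        for s, e, sc in zip(sub["start"], sub["end"], sub["score"]):
            s, e = int(s), min(int(e), length)
            b0, b1 = s // segment, (e - 1) // segment
            for b in range(b0, b1 + 1):
                lo = max(s, b * segment)
                hi = min(e, (b + 1) * segment)
                wsum[b] += sc * (hi - lo)
                cov[b] += hi - lo
        for b in range(n_seg):
            if cov[b] > 0:
                rows.append((chrom, b * segment, min((b + 1) * segment, length),
                             wsum[b] / cov[b]))
            else:
                n_uncovered += 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    out.attrs["n_uncovered"] = n_uncovered
    return out


def quantile_sets(segments: pd.DataFrame, n_sets: int = 50) -> pd.DataFrame:
    """Rank segments by score into equally sized conservation sets.

    Ascending score (ties broken by coordinate), split into contiguous
    blocks whose sizes differ by at most one; the remainder is spread over
    the lowest sets.  Adds a ``set`` column with index 0 (fastest changing)
    to ``n_sets - 1`` (most conserved).
    """
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    if len(segments) < n_sets:
        raise ValueError("fewer segments than sets")
    ordered = segments.sort_values(["score", "chrom", "start"], kind="mergesort").reset_index(drop=True)
    n = len(ordered)
    base, rem = divmod(n, n_sets)
    sizes = [base + 1 if i < rem else base for i in range(n_sets)]
    labels = np.repeat(np.arange(n_sets), sizes)
    ordered["set"] = labels
    return ordered


@dataclass
class OrthologyMap:
    """One-to-one aligned interval pairs between two assemblies.

    ``pairs`` columns: src_chrom, src_start, src_end, tgt_chrom, tgt_start,
    tgt_end, identity.  Reciprocal-best filtering is assumed upstream: no
    source interval maps twice.  The identity threshold is applied at query
    time.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start",
               "tgt_end", "identity"]
        missing = [c for c in req if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"orthology map missing columns {missing}")
        p = self.pairs
        if ((p["identity"] < 0) | (p["identity"] > 1)).any():
            raise ValueError("identity weights must be in [0, 1]")
        for chrom, sub in p.groupby("src_chrom"):
            s = sub.sort_values("src_start")
            if (s["src_start"].to_numpy()[1:] < s["src_end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping source intervals on {chrom}")

    @classmethod
    def read(cls, path) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["src_chrom", "src_start", "src_end", "tgt_chrom",
                                "tgt_start", "tgt_end", "identity"])
        return cls(df)

    def write(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", header=False, index=False)


def lift_regions(
    omap: OrthologyMap,
    regions: pd.DataFrame,
    min_identity: float = 0.65,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project source regions into target coordinates through the map.

    Region pieces intersecting a map pair with identity >= ``min_identity``
    are projected piecewise-linearly (offset-scaled when source and target
    pair lengths differ); pieces below the identity threshold or outside the
    map are reported in the unmapped table.  Returns (mapped, unmapped);
    mapped rows carry the source coordinates alongside the target ones.
    """
    usable = omap.pairs[omap.pairs["identity"] >= min_identity]
    by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for chrom, sub in usable.groupby("src_chrom"):
        s = sub.sort_values("src_start")
        by_chrom[chrom] = {
            "ss": s["src_start"].to_numpy(np.int64),
            "se": s["src_end"].to_numpy(np.int64),
            "ts": s["tgt_start"].to_numpy(np.int64),
            "te": s["tgt_end"].to_numpy(np.int64),
            "tc": s["tgt_chrom"].to_numpy(),
        }
    all_src = set(omap.pairs["src_chrom"])
    mapped_rows, unmapped_rows = [], []
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        start, end = int(start), int(end)
        if end <= start:
            raise ValueError("zero-length region")
        if chrom not in all_src:
            raise ValueError(f"region on chromosome {chrom!r} unknown to the map")
        pairs = by_chrom.get(chrom)
        pos = start
        if pairs is not None:
            ss, se = pairs["ss"], pairs["se"]
            i0 = int(np.searchsorted(se, start, side="right"))
            i1 = int(np.searchsorted(ss, end, side="left"))
            for i in range(i0, i1):
                ps, pe = int(ss[i]), int(se[i])
                lo, hi = max(pos, ps), min(end, pe)
                if hi <= lo:
                    continue
                if lo > pos:
                    unmapped_rows.append((chrom, pos, lo))
                scale = (pairs["te"][i] - pairs["ts"][i]) / (pe - ps)
                t0 = int(round(pairs["ts"][i] + (lo - ps) * scale))
                t1 = int(round(pairs["ts"][i] + (hi - ps) * scale))
                if t1 > t0:
                    mapped_rows.append((pairs["tc"][i], t0, t1, chrom, lo, hi))
                else:
                    unmapped_rows.append((chrom, lo, hi))
                pos = hi
        if pos < end:
            unmapped_rows.append((chrom, pos, end))
    mapped = pd.DataFrame(
        mapped_rows,
        columns=["chrom", "start", "end", "src_chrom", "src_start", "src_end"],
    )
    unmapped = pd.DataFrame(unmapped_rows, columns=["chrom", "start", "end"])
    return mapped, unmapped


def epi_conservation_rate(
    lifted_regions: pd.DataFrame,
    target_segmentation: Segmentation,
    state: str,
) -> pd.Series:
    """Per-region conservation rate of a state in the target species.

    rate = bases of the lifted region covered by the same state in the
    target segmentation, over the region length; 0 when there is no overlap,
    1 when the region is completely occupied.
    """
    target = target_segmentation.state_intervals(state)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if not target.empty:
        for chrom, sub in flatten(target).groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            cum = np.concatenate([[0], np.cumsum(e - s)])
            by_chrom[chrom] = (s, e, cum)

    def _cov_up_to(chrom: str, x: int) -> int:
        """Covered bases of the target state in [0, x)."""
        if chrom not in by_chrom:
            return 0
        s, e, cum = by_chrom[chrom]
        i = int(np.searchsorted(s, x, side="right"))
        full = int(cum[i])
        if i > 0 and e[i - 1] > x:
            full -= int(e[i - 1] - x)
        return full

    rates = []
    for chrom, start, end in zip(
        lifted_regions["chrom"], lifted_regions["start"], lifted_regions["end"]
    ):
        length = int(end) - int(start)
        if length <= 0:
            raise ValueError("zero-length lifted region")
        ov = _cov_up_to(chrom, int(end)) - _cov_up_to(chrom, int(start))
        rates.append(ov / length)
    return pd.Series(rates, index=lifted_regions.index, name="rate")


def conservation_curve(
    regions: pd.DataFrame,
    rates: pd.Series,
    segment_sets: pd.DataFrame,
    n_sets: int = 50,
) -> pd.Series:
    """Mean epi-conservation rate per sequence-conservation set.

    Each region (source coordinates) is assigned to the set of the 200-bp
    segment containing its midpoint; sets with no regions are NaN.
    """
    if regions.empty:
        raise ValueError("no regions")
    seg_size = int(segment_sets["end"].iloc[0] - segment_sets["start"].iloc[0])
    lookup = {
        (c, s): st
        for c, s, st in zip(segment_sets["chrom"], segment_sets["start"], segment_sets["set"])
    }
    assigned = []
    for _, r in regions.iterrows():
        mid = (int(r["start"]) + int(r["end"])) // 2
        assigned.append(lookup.get((r["chrom"], (mid // seg_size) * seg_size), -1))
    df = pd.DataFrame({"set": assigned, "rate": rates.to_numpy()})
    df = df[df["set"] >= 0]
    curve = df.groupby("set")["rate"].mean().reindex(range(n_sets))
    curve.name = "epi_conservation_rate"
    return curve


def pooled_conservation_curve(
    source_segmentation: Segmentation,
    target_segmentation: Segmentation,
    omap: OrthologyMap,
    segment_sets: pd.DataFrame,
    min_identity: float = 0.65,
    n_sets: int = 50,
    states: Sequence[str] | None = None,
) -> pd.Series:
    """End-to-end epi-conservation curve pooled over non-quiescent states.

    Lifts each state's source regions through the map, scores their
    conservation rate against the target segmentation, and averages rates
    per sequence-conservation set (regions binned by the set of their
    source-coordinate midpoint segment).
    """
    qui = source_segmentation.catalog.quiescent
    use = states if states is not None else [
        s for s in source_segmentation.catalog.labels if s != qui
    ]
    reg_parts, rate_parts = [], []
    for state in use:
        regs = source_segmentation.state_intervals(state)
        if regs.empty:
            continue
        mapped, _ = lift_regions(omap, regs, min_identity=min_identity)
        if mapped.empty:
            continue
        rates = epi_conservation_rate(mapped, target_segmentation, state)
        reg_parts.append(
            mapped[["src_chrom", "src_start", "src_end"]].rename(
                columns={"src_chrom": "chrom", "src_start": "start", "src_end": "end"}
            )
        )
        rate_parts.append(rates)
    if not reg_parts:
        raise ValueError("no lifted regions to score")
    return conservation_curve(
        pd.concat(reg_parts, ignore_index=True),
        pd.concat(rate_parts, ignore_index=True),
        segment_sets,
        n_sets=n_sets,
    )


def expression_conservation_sets(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    n_sets: int = 50,
) -> pd.DataFrame:
    """Stratify orthologous genes by cross-species expression divergence.

    ``expr_a`` and ``expr_b`` are gene x replicate TPM tables for the two
    species (same gene index, >= 2 replicates each).  A two-sample t-test
    per gene compares the species' replicate values; genes are sorted by
    ascending p (set 0 = biggest expression difference) and cut into
    ``n_sets`` equal sets.  Returns a table (gene, p, set).
    """
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per species")
    common = expr_a.index.intersection(expr_b.index)
    pvals = []
    for g in common:
        a = expr_a.loc[g].to_numpy(dtype=float)
        b = expr_b.loc[g].to_numpy(dtype=float)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if math.isnan(p):
                p = 1.0
        pvals.append(p)
    out = pd.DataFrame({"gene": common, "p": pvals})
    out = out.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    n = len(out)
    base, rem = divmod(n, n_sets)
    sizes = [base + 1 if i < rem else base for i in range(n_sets)]
    out["set"] = np.repeat(np.arange(n_sets), sizes)
    return out


def mean_rate_around_tss(
    gene_sets: pd.DataFrame,
    genes: GeneTable,
    lifted_regions: pd.DataFrame,
    rates: pd.Series,
    half_window: int = 10_000,
) -> pd.Series:
    """Mean epi-conservation rate of state regions within TSS +/- half_window,
    per expression-divergence gene set (source-coordinate regions)."""
    gene_info = genes.genes.set_index("gene_id")
    mids = (lifted_regions["src_start"].to_numpy() + lifted_regions["src_end"].to_numpy()) // 2
    chroms = lifted_regions["src_chrom"].to_numpy()
    out = {}
    for s, sub in gene_sets.groupby("set"):
        vals = []
        for g in sub["gene"]:
            if g not in gene_info.index:
                continue
            gi = gene_info.loc[g]
            sel = (chroms == gi["chrom"]) & (np.abs(mids - int(gi["tss"])) <= half_window)
            if sel.any():
                vals.append(float(rates.to_numpy()[sel].mean()))
        out[s] = float(np.mean(vals)) if vals else float("nan")
    return pd.Series(out, name="mean_rate")
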