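"""Windowed FST selection signatures, their chromatin-state enrichment, and
the genotype cyclical-permutation GWAS enrichment test.

FST is the Hudson estimator aggregated per window as a ratio of averages
(mean numerator over mean denominator across SNPs), computed in 10-kb
non-overlapping windows by default; the top 5% of windows are the candidate
selection signatures.  GWAS enrichment rotates the SNP-to-annotation
membership vector along the genome-ordered SNP list, which preserves the
local correlation structure of both the annotation and the association
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, fisher_enrichment_test, fold_enrichment
from .genome import FeatureSet, GenomeAssembly
from .intervals import flatten
from .io import bundled_path

__all__ = [
    "hudson_fst_components",
    "windowed_fst",
    "top_fraction_windows",
    "selection_enrichment",
    "PermutationResult",
    "cyclical_permutation_test",
    "eqtl_enrichment",
    "load_wgs_design",
    "validate_wgs_design",
]


def hudson_fst_components(
    p1: np.ndarray, p2: np.ndarray, n1: int, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Hudson FST numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 sampled alleles per population")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def windowed_fst(
    freqs: pd.DataFrame,
    window: int = 10_000,
    step: int | None = None,
) -> pd.DataFrame:
    """Window-level Hudson FST from a per-SNP allele-frequency table.

    ``freqs`` columns: chrom, pos, p1, p2, n1, n2 (frequencies of either
    allele in two populations, with allele sample sizes).  The window FST is
    the ratio of averages: mean numerator / mean denominator over the SNPs
    in the window; monomorphic windows (zero denominator) get FST 0 and
    windows without SNPs are omitted.  Windows tile each chromosome from 0
    at the given step (default: non-overlapping).
    """
    step = step or window
    rows = []
    for chrom, sub in freqs.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        num, den = hudson_fst_components(
            sub["p1"].to_numpy(), sub["p2"].to_numpy(),
            int(sub["n1"].iloc[0]), int(sub["n2"].iloc[0]),
        )
        last = int(pos.max())
        start = 0
        while start <= last:
            in_w = (pos >= start) & (pos < start + window)
            if in_w.any():
                d = den[in_w].mean()
                fst = float(num[in_w].mean() / d) if d > 0 else 0.0
                rows.append((chrom, start, start + window, fst, int(in_w.sum())))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "n_snps"])


def top_fraction_windows(table: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Top-FST windows as a selection-signature interval set.

    Selects ceil(fraction * n) windows by descending FST; ties resolved by
    genomic order (a warning is emitted when the cut falls inside a tie).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if table.empty:
        raise ValueError("empty FST window table")
    k = math.ceil(fraction * len(table))
    ordered = table.reset_index(drop=True)
    ordered = ordered.sort_values(
        ["fst"], ascending=False, kind="mergesort"
    )  # stable: genomic order preserved within ties
    cut = ordered.iloc[:k]
    if len(ordered) > k and ordered.iloc[k]["fst"] == cut.iloc[-1]["fst"]:
        import warnings

        warnings.warn("FST tie at the selection cutoff; genomic-order tie-break applied")
    return cut[["chrom", "start", "end", "fst"]].sort_values(["chrom", "start"]).reset_index(drop=True)


def selection_enrichment(
    signatures: pd.DataFrame,
    state_intervals: pd.DataFrame,
    assembly: GenomeAssembly,
    state: str = "state",
    fisher: bool = False,
) -> EnrichmentResult:
    """Fold enrichment (C/A)/(B/D) of selection signatures in a state."""
    feat = FeatureSet("selection_signatures", signatures[["chrom", "start", "end"]])
    res = fold_enrichment(state_intervals, feat, assembly, state=state)
    if fisher:
        p = fisher_enrichment_test(state_intervals, feat, assembly)
        res = EnrichmentResult(res.state, res.feature, res.A, res.B, res.C, res.D,
                               res.fold_enrichment, p)
    return res


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    seed: int
    n_member_snps: int


def cyclical_permutation_test(
    snps: pd.DataFrame,
    annotation: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mean",
) -> PermutationResult:
    """Genotype cyclical-permutation test of GWAS signal in an annotation.

    ``snps`` is a genome-ordered table (chrom, pos, stat); the membership
    vector marks SNPs falling in the annotation intervals.  The observed
    statistic is the mean (or sum) of member-SNP association statistics;
    each permutation rotates the membership vector by a uniform random
    offset in [1, n-1] along the SNP list and recomputes.  The empirical p
    is (1 + #{null >= observed}) / (1 + n_perm).
    """
    if len(snps) < 100:
        raise ValueError("need at least 100 SNPs")
    if statistic not in {"mean", "sum"}:
        raise ValueError("statistic must be 'mean' or 'sum'")
    stats_vec = snps["stat"].to_numpy(dtype=float)
    n = len(stats_vec)
    member = np.zeros(n, dtype=bool)
    ann = flatten(annotation[["chrom", "start", "end"]])
    for chrom, sub in ann.groupby("chrom", sort=False):
        pos = snps.loc[snps["chrom"] == chrom, "pos"].to_numpy()
        idx = snps.index[snps["chrom"] == chrom].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        member[idx[ok]] = True
    m = int(member.sum())
    if m == 0 or m == n:
        raise ValueError("annotation covers no SNP or every SNP")
    member_idx = np.flatnonzero(member)
    # precompute the statistic under every possible rotation offset, then
    # sample offsets; identical to rotating the membership vector since
    # sum_i stat[(i + off) % n] * member[i] only depends on the offset
    shifted = (member_idx[None, :] + np.arange(n)[:, None]) % n
    all_sums = stats_vec[shifted].sum(axis=1)
    observed = all_sums[0] / m if statistic == "mean" else all_sums[0]
    rng = np.random.default_rng(seed)
    offsets = rng.integers(1, n, size=n_perm)
    null = all_sums[offsets] / m if statistic == "mean" else all_sums[offsets]
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationResult(float(observed), null, float(p), n_perm, seed, m)


def eqtl_enrichment(
    eqtl_snps: pd.DataFrame,
    state_intervals: pd.DataFrame,
    assembly: GenomeAssembly,
    state: str = "state",
) -> EnrichmentResult:
    """Fold enrichment of significant eQTL SNPs (1-bp features) in a state."""
    if eqtl_snps.empty:
        raise ValueError("empty eQTL SNP set")
    if "start" in eqtl_snps.columns:
        pts = eqtl_snps[["chrom", "start", "end"]]
    else:
        pts = pd.DataFrame(
            {"chrom": eqtl_snps["chrom"], "start": eqtl_snps["pos"], "end": eqtl_snps["pos"] + 1}
        )
    feat = FeatureSet("eqtl_snps", pts)
    return fold_enrichment(state_intervals, feat, assembly, state=state)


def load_wgs_design(path=None) -> pd.DataFrame:
    """The wild/domestic WGS cohort design table (population, status, n)."""
    p = path if path is not None else bundled_path("wgs_design.tsv")
    return pd.read_csv(p, sep="\t")


def validate_wgs_design(design: pd.DataFrame, expected_total: int = 406) -> int:
    """Validate the WGS design table; returns the verified sample total.

    Requires positive per-cell counts, the four population/status cells, and
    a grand total matching ``expected_total``.
    """
    if (design["n_samples"] <= 0).any():
        raise ValueError("sample counts must be positive")
    if design.duplicated(["population", "status"]).any():
        raise ValueError("duplicate design cells")
    total = int(design["n_samples"].sum())
    if total != expected_total:
        raise ValueError(f"design total {total} != expected {expected_total}")
    return total
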