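"""Synthetic multi-tissue epigenome generator with planted ground truth.

Emulates the study design the analyses expect: 14 tissue segmentations over
a 15-state vocabulary (5 intestinal, 3 brain, 6 singleton tissues), with
planted all-common / gut-common / brain-common / tissue-specific regulatory
elements; gene expression with planted tissue-specific genes; CTCF loops
holding correlated enhancer-gene pairs; GWAS statistics inflated inside a
chosen annotation; shifted-FST windows; and a two-assembly orthology setting
with class-dependent chromatin-state turnover.

Every generator is a pure function of (config, stage-specific substream of
the seed), so stages can be regenerated independently and outputs are
byte-identical across runs.  The planted truth is serialized alongside the
data and is never consumed by the analysis stages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import OrthologyMap
from .genome import GeneTable, GenomeAssembly, Segmentation, StateCatalog
from .specificity import (
    BRAIN_TISSUES,
    DEFAULT_TISSUE_GROUPS,
    DEFAULT_TISSUES,
    INTESTINAL_TISSUES,
    ExpressionMatrix,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "make_assembly",
    "make_gene_table",
    "simulate_segmentations",
    "simulate_expression",
    "simulate_enhancer_signal_and_loops",
    "simulate_gwas_and_fst",
    "simulate_orthology_pair",
]

_STAGE_KEYS = {"segmentation": 0, "expression": 1, "loops": 2, "gwas": 3, "orthology": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],)))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring its design."""

    seed: int = 1
    chrom_lengths: tuple[tuple[str, int], ...] = (("chrA", 6_000_000), ("chrB", 4_000_000))
    bin_size: int = 200
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    groups: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_GROUPS)
    )
    # planted regulatory elements (200-bp-multiple intervals)
    element_state: str = "EnhA"
    n_all_common: int = 20
    n_gut_common: int = 20
    n_brain_common: int = 20
    n_specific_per_tissue: int = 5
    n_background: int = 100
    mean_len_bins: float = 3.0   # geometric mean length in bins (~600 bp)
    max_len_bins: int = 10
    plant_tss_state: bool = True  # constitutive TssA at every gene TSS
    # expression
    n_genes: int = 1000
    n_tse_per_tissue: int = 10
    mu_base: float = 3.0
    sigma: float = 1.0
    delta: float = 5.0           # TSE effect on log2(TPM+1), in units of sigma
    # enhancer-gene linking
    n_loops: int = 6
    loop_span: int = 100_000
    n_decoys_per_loop: int = 4
    signal_gain: float = 2.0
    signal_noise_sd: float = 0.0
    # GWAS / FST
    n_snps: int = 2000
    snp_spacing: int | None = None  # default: first chromosome length / n_snps
    gwas_inflation: float = 3.0
    gwas_annotation_frac: float = 0.10
    n_annotation_blocks: int = 20
    fst_window: int = 10_000
    fst_shift: float = 0.4
    fst_planted_frac: float = 0.05
    # orthology / conservation
    ortho_chrom_length: int = 2_000_000
    n_conservation_sets: int = 50
    flip_profile: tuple[float, ...] | None = None  # length n_sets; default U-shape
    low_identity_frac: float = 0.10
    ortho_pair_size: int = 1000

    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly("synthetic", tuple(self.chrom_lengths))

    def validate(self) -> None:
        if self.gwas_inflation < 1:
            raise ValueError("GWAS inflation must be >= 1")
        if self.delta <= 0:
            raise ValueError("TSE effect delta must be positive")
        if self.n_genes < self.n_tse_per_tissue * len(self.tissues):
            raise ValueError("gene count below planted TSE count x tissues")
        prof = self.default_flip_profile()
        if ((prof < 0) | (prof > 1)).any():
            raise ValueError("flip rates must lie in [0, 1]")

    def default_flip_profile(self) -> np.ndarray:
        """State-turnover probability per conservation set (U-shaped default:
        high turnover for neutral middle sets, low at both extremes)."""
        if self.flip_profile is not None:
            return np.asarray(self.flip_profile, dtype=float)
        x = np.linspace(-1, 1, self.n_conservation_sets)
        return 0.75 - 0.65 * x * x


@dataclass
class PlantedTruth:
    """Ground truth written next to the data; never read by analyses."""

    elements: pd.DataFrame          # chrom,start,end,state,category,tissues
    tse_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    links: pd.DataFrame | None = None            # enhancer, gene
    gwas_annotation: pd.DataFrame | None = None  # chrom,start,end
    fst_planted: pd.DataFrame | None = None      # chrom,start,end
    flip_profile: np.ndarray | None = None
    segment_class: pd.DataFrame | None = None    # chrom,start,end,set

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.elements.assign(
            tissues=self.elements["tissues"].map(lambda t: ",".join(t))
        ).to_csv(os.path.join(outdir, "elements.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "tse_genes.tsv"), "w") as fh:
            for t in sorted(self.tse_genes):
                fh.write(f"{t}\t{','.join(self.tse_genes[t])}\n")
        if self.links is not None:
            self.links.to_csv(os.path.join(outdir, "links.tsv"), sep="\t", index=False)
        if self.gwas_annotation is not None:
            self.gwas_annotation.to_csv(
                os.path.join(outdir, "gwas_annotation.bed"), sep="\t", index=False, header=False
            )
        if self.fst_planted is not None:
            self.fst_planted.to_csv(
                os.path.join(outdir, "fst_planted.bed"), sep="\t", index=False, header=False
            )
        if self.flip_profile is not None:
            pd.Series(self.flip_profile, name="flip_rate").to_csv(
                os.path.join(outdir, "flip_profile.tsv"), sep="\t", index_label="set"
            )
        if self.segment_class is not None:
            self.segment_class.to_csv(
                os.path.join(outdir, "segment_class.tsv"), sep="\t", index=False
            )

    @classmethod
    def read(cls, outdir: str) -> "PlantedTruth":
        elements = pd.read_csv(os.path.join(outdir, "elements.tsv"), sep="\t")
        elements["tissues"] = elements["tissues"].map(lambda s: tuple(s.split(",")))
        tse: dict[str, tuple[str, ...]] = {}
        tse_path = os.path.join(outdir, "tse_genes.tsv")
        if os.path.exists(tse_path):
            with open(tse_path) as fh:
                for line in fh:
                    t, ids = line.rstrip("\n").split("\t")
                    tse[t] = tuple(ids.split(","))
        def _opt(name, **kw):
            p = os.path.join(outdir, name)
            return pd.read_csv(p, sep="\t", **kw) if os.path.exists(p) else None
        links = _opt("links.tsv")
        ann = _opt("gwas_annotation.bed", header=None, names=["chrom", "start", "end"])
        fst = _opt("fst_planted.bed", header=None, names=["chrom", "start", "end"])
        prof = _opt("flip_profile.tsv")
        seg = _opt("segment_class.tsv")
        return cls(
            elements, tse, links, ann, fst,
            prof["flip_rate"].to_numpy() if prof is not None else None, seg,
        )


def make_gene_table(config: SimulationConfig) -> GeneTable:
    """Evenly spaced genes over the assembly, alternating strands.

    TSS positions sit on the bin grid so planted promoter states align with
    segmentation bins; placement is deterministic (no randomness needed).
    """
    asm = config.assembly()
    b = config.bin_size
    spacing = (asm.total_length // config.n_genes // b) * b
    rows = []
    i = 0
    for chrom, length in asm.chromosomes:
        pos = spacing // 2
        while pos + spacing // 2 < length and i < config.n_genes:
            strand = "+" if i % 2 == 0 else "-"
            tss = (pos // b) * b
            tes = tss + 4 * b if strand == "+" else tss - 4 * b
            rows.append((f"gene{i:04d}", chrom, strand, tss, max(0, tes), "protein_coding"))
            pos += spacing
            i += 1
    return GeneTable(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "tes", "biotype"]
    ))


def make_assembly(config: SimulationConfig) -> GenomeAssembly:
    return config.assembly()


_BACKGROUND_STATES = ("TssAHet", "TxFlnk", "TxFlnkWk", "TxFlnkHet", "EnhAWk",
                      "EnhAHet", "EnhPois", "ATAC_Is", "TssBiv", "Repr", "ReprWk")


def _draw_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    k = int(rng.geometric(1.0 / config.mean_len_bins))
    return min(max(k, 1), config.max_len_bins)


def simulate_segmentations(
    config: SimulationConfig,
) -> tuple[dict[str, Segmentation], PlantedTruth, GeneTable]:
    """Per-tissue segmentations with planted sharing structure.

    Elements are 200-bp-multiple intervals planted without overlap in four
    categories (all-common, gut-common, brain-common, tissue-specific) in the
    configured element state, plus background elements of other non-quiescent
    states carried by random tissue subsets; unclaimed bins are quiescent.
    Optionally every gene TSS bin carries a constitutive active-promoter
    state in all tissues.
    """
    config.validate()
    rng = _stage_rng(config.seed, "segmentation")
    asm = config.assembly()
    catalog = StateCatalog()
    genes = make_gene_table(config)
    b = config.bin_size
    occupied: dict[str, set[int]] = {c: set() for c, _ in asm.chromosomes}
    records: list[tuple] = []

    if config.plant_tss_state:
        for _, g in genes.genes.iterrows():
            tss_bin = int(g["tss"]) // b
            occupied[g["chrom"]].add(tss_bin)
            records.append(
                (g["chrom"], tss_bin * b, (tss_bin + 1) * b, "TssA", "tss", tuple(config.tissues))
            )

    chrom_names = [c for c, _ in asm.chromosomes]
    chrom_bins = {c: l // b for c, l in asm.chromosomes}
    weights = np.array([chrom_bins[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()

    def _place(n_bins: int) -> tuple[str, int] | None:
        for _ in range(200):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            start_bin = int(rng.integers(0, chrom_bins[chrom] - n_bins))
            span = range(start_bin, start_bin + n_bins)
            if not any(s in occupied[chrom] for s in span):
                occupied[chrom].update(span)
                return chrom, start_bin
        return None

    categories: list[tuple[str, tuple[str, ...], str]] = []
    categories += [("all_common", tuple(config.tissues), config.element_state)] * config.n_all_common
    categories += [("gut_common", INTESTINAL_TISSUES, config.element_state)] * config.n_gut_common
    categories += [("brain_common", BRAIN_TISSUES, config.element_state)] * config.n_brain_common
    for t in config.tissues:
        categories += [(f"{t}_specific", (t,), config.element_state)] * config.n_specific_per_tissue
    for _ in range(config.n_background):
        size = int(rng.integers(2, len(config.tissues)))
        subset = tuple(sorted(rng.choice(config.tissues, size=size, replace=False)))
        state = str(rng.choice(_BACKGROUND_STATES))
        categories.append(("background", subset, state))

    total_bins = sum(chrom_bins.values())
    demand = len(categories) * config.mean_len_bins
    if demand > 0.5 * total_bins:
        raise ValueError("requested element mass exceeds genome capacity")

    for category, tissues, state in categories:
        n_bins = _draw_length(rng, config)
        placed = _place(n_bins)
        if placed is None:
            raise ValueError("could not place element; genome too crowded")
        chrom, start_bin = placed
        records.append(
            (chrom, start_bin * b, (start_bin + n_bins) * b, state, category, tissues)
        )

    elements = pd.DataFrame(
        records, columns=["chrom", "start", "end", "state", "category", "tissues"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    segmentations: dict[str, Segmentation] = {}
    for t in config.tissues:
        mine = elements[elements["tissues"].map(lambda tt: t in tt)]
        rows = []
        for chrom, length in asm.chromosomes:
            sub = mine[mine["chrom"] == chrom].sort_values("start")
            pos = 0
            for s, e, st in zip(sub["start"], sub["end"], sub["state"]):
                if s > pos:
                    rows.append((chrom, pos, s, "Qui"))
                rows.append((chrom, s, e, st))
                pos = e
            if pos < length:
                rows.append((chrom, pos, length, "Qui"))
        seg = Segmentation(t, pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]),
                           asm, catalog, b)
        segmentations[t] = seg
    truth = PlantedTruth(elements)
    return segmentations, truth, genes


def simulate_expression(
    config: SimulationConfig, truth: PlantedTruth, genes: GeneTable | None = None
) -> ExpressionMatrix:
    """Gene x tissue TPM with planted tissue-specific expression.

    log2(TPM+1) of every gene-tissue cell is Normal(mu_base, sigma); planted
    TSE genes gain delta * sigma in their focal tissue.  The planted ids are
    recorded in the truth.
    """
    config.validate()
    rng = _stage_rng(config.seed, "expression")
    genes = genes if genes is not None else make_gene_table(config)
    ids = list(genes.genes["gene_id"])
    tissues = list(config.tissues)
    x = rng.normal(config.mu_base, config.sigma, size=(len(ids), len(tissues)))
    chosen = rng.choice(len(ids), size=config.n_tse_per_tissue * len(tissues), replace=False)
    tse: dict[str, tuple[str, ...]] = {}
    for j, t in enumerate(tissues):
        block = chosen[j * config.n_tse_per_tissue : (j + 1) * config.n_tse_per_tissue]
        x[block, j] += config.delta * config.sigma
        tse[t] = tuple(ids[i] for i in sorted(block))
    tpm = np.maximum(np.exp2(x) - 1.0, 0.0)
    truth.tse_genes = tse
    return ExpressionMatrix(pd.DataFrame(tpm, index=ids, columns=tissues),
                            groups=dict(config.groups))


def simulate_enhancer_signal_and_loops(
    config: SimulationConfig,
    truth: PlantedTruth,
    expr: ExpressionMatrix,
    genes: GeneTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Enhancer x tissue signal, a CTCF motif table, and planted links.

    Loop windows are laid head-to-tail on the first chromosome, each framed
    by a convergent motif pair (+ anchor then - anchor).  Inside each loop
    one planted enhancer tracks one resident gene's expression
    (signal = gain * TPM + noise); decoy enhancers in the same loop carry
    independent noise.  Returns (signal table with chrom/start/end columns,
    motif hit table, planted link list).
    """
    from .linking import MotifHit

    config.validate()
    rng = _stage_rng(config.seed, "loops")
    genes = genes if genes is not None else make_gene_table(config)
    asm = config.assembly()
    chrom = asm.chromosomes[0][0]
    chrom_len = asm.chromosomes[0][1]
    span = config.loop_span
    if span < 4000:
        raise ValueError("loop span too small to hold anchors and elements")
    if (config.n_loops + 1) * span > chrom_len:
        raise ValueError("loops do not fit on the first chromosome")
    gt = genes.genes
    tissues = list(config.tissues)
    motif_rows = []
    signal_rows = []
    link_rows = []
    gap = span // 2
    for k in range(config.n_loops):
        left = gap + k * (span + gap)
        right = left + span
        motif_rows.append((chrom, left, left + 19, "+", 20.0))
        motif_rows.append((chrom, right - 19, right, "-", 20.0))
        resident = gt[(gt["chrom"] == chrom) & (gt["tss"] >= left + 200) & (gt["tss"] < right - 200)]
        if resident.empty:
            continue
        g = resident["gene_id"].iloc[int(rng.integers(0, len(resident)))]
        gvec = expr.tpm.loc[g, tissues].to_numpy(dtype=float)
        e_start = left + 1000 + int(rng.integers(0, (span - 4000) // 200)) * 200
        eid = f"enh{k:03d}_linked"
        sig = config.signal_gain * gvec + rng.normal(0, config.signal_noise_sd, len(tissues))
        signal_rows.append((eid, chrom, e_start, e_start + 400, *sig))
        link_rows.append((eid, g))
        for d in range(config.n_decoys_per_loop):
            d_start = left + 1000 + int(rng.integers(0, (span - 4000) // 200)) * 200
            did = f"enh{k:03d}_decoy{d}"
            noise = rng.normal(5.0, 1.0, len(tissues))
            signal_rows.append((did, chrom, d_start, d_start + 400, *noise))
    signal = pd.DataFrame(
        signal_rows, columns=["enhancer", "chrom", "start", "end", *tissues]
    ).set_index("enhancer")
    motifs = [MotifHit(*r) for r in motif_rows]
    truth.links = pd.DataFrame(link_rows, columns=["enhancer", "gene"])
    return signal, pd.DataFrame(motif_rows, columns=["chrom", "start", "end", "strand", "score"]), motifs


def simulate_gwas_and_fst(
    config: SimulationConfig, truth: PlantedTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """SNP association statistics and windowed FST values with planted signal.

    SNPs sit on a regular grid over the first chromosome; their
    chi-square(1 df) statistics are scaled by the inflation factor inside a
    planted annotation built from ``n_annotation_blocks`` equal blocks
    holding ~``gwas_annotation_frac`` of SNPs.  FST windows follow a
    Beta(0.5, 9.5) baseline with ``fst_shift`` added inside planted
    windows; when the truth carries planted elements, the shifted windows
    are drawn among windows overlapping the element state, so selection
    signatures are genuinely state-enriched.  Also returns a per-SNP
    two-population allele-frequency table whose window FST reproduces the
    planted contrast.
    """
    config.validate()
    rng = _stage_rng(config.seed, "gwas")
    asm = config.assembly()
    chrom, chrom_len = asm.chromosomes[0]
    spacing = config.snp_spacing or chrom_len // config.n_snps
    positions = np.arange(config.n_snps) * spacing + spacing // 2
    if positions[-1] >= chrom_len:
        raise ValueError("SNP grid exceeds the first chromosome")
    stats_vec = rng.chisquare(1, size=config.n_snps)
    n_member = int(round(config.gwas_annotation_frac * config.n_snps))
    per_block = max(1, n_member // config.n_annotation_blocks)
    block_starts = rng.choice(
        config.n_snps - per_block, size=config.n_annotation_blocks, replace=False
    )
    member = np.zeros(config.n_snps, dtype=bool)
    for bs in np.sort(block_starts):
        member[bs : bs + per_block] = True
    stats_vec[member] *= config.gwas_inflation
    snps = pd.DataFrame({"chrom": chrom, "pos": positions, "stat": stats_vec})
    ann_rows = []
    idx = np.flatnonzero(member)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for blk in splits:
        ann_rows.append(
            (chrom, int(positions[blk[0]]) - 1, int(positions[blk[-1]]) + 1)
        )
    annotation = pd.DataFrame(ann_rows, columns=["chrom", "start", "end"])

    w = config.fst_window
    n_windows = chrom_len // w
    fst = rng.beta(0.5, 9.5, size=n_windows)
    n_planted = max(1, int(round(config.fst_planted_frac * n_windows)))
    elements = truth.elements
    candidates = np.arange(n_windows)
    if elements is not None and len(elements):
        hits = elements[(elements["chrom"] == chrom)
                        & (elements["state"] == config.element_state)]
        overlap_windows = sorted({
            widx
            for s, e in zip(hits["start"], hits["end"])
            for widx in range(int(s) // w, min((int(e) - 1) // w + 1, n_windows))
        })
        if overlap_windows:
            candidates = np.asarray(overlap_windows)
    n_planted = min(n_planted, len(candidates))
    planted_idx = np.sort(rng.choice(candidates, size=n_planted, replace=False))
    fst[planted_idx] = np.minimum(fst[planted_idx] + config.fst_shift, 1.0)
    windows = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_windows) * w,
            "end": (np.arange(n_windows) + 1) * w,
            "fst": fst,
        }
    )
    planted_windows = windows.iloc[planted_idx][["chrom", "start", "end"]].reset_index(drop=True)

    # allele-frequency route to the same contrast: divergent frequencies in
    # planted windows, shared frequencies elsewhere
    window_of = np.minimum(positions // w, n_windows - 1)
    in_planted = np.isin(window_of, planted_idx)
    base = rng.uniform(0.2, 0.8, size=config.n_snps)
    p1 = base.copy()
    p2 = np.clip(base + rng.normal(0, 0.02, size=config.n_snps), 0.0, 1.0)
    p1[in_planted] = rng.uniform(0.85, 1.0, size=int(in_planted.sum()))
    p2[in_planted] = rng.uniform(0.0, 0.15, size=int(in_planted.sum()))
    freqs = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "p1": p1, "p2": p2, "n1": 100, "n2": 100}
    )
    truth.gwas_annotation = annotation
    truth.fst_planted = planted_windows
    return snps, windows, freqs


def simulate_orthology_pair(
    config: SimulationConfig,
) -> tuple[Segmentation, Segmentation, OrthologyMap, pd.DataFrame, PlantedTruth]:
    """A source/target "species" pair with class-dependent state turnover.

    The source chromosome is segmented into iid per-200-bp states; each
    segment carries a conservation score whose rank defines its set (0 =
    fastest changing).  The target segmentation is a copy in which each
    segment's state is replaced by a random different state with probability
    given by the flip profile of its set.  The orthology map pairs equal
    coordinates block-by-block, with a planted fraction of blocks below the
    0.65 identity threshold; the score track is the per-segment score as
    bedGraph rows.
    """
    config.validate()
    rng = _stage_rng(config.seed, "orthology")
    b = 200
    L = (config.ortho_chrom_length // b) * b
    n_seg = L // b
    src_asm = GenomeAssembly("source", (("src1", L),))
    tgt_asm = GenomeAssembly("target", (("tgt1", L),))
    catalog = StateCatalog()
    labels = list(catalog.labels)
    probs = np.full(len(labels), 0.4 / (len(labels) - 1))
    probs[labels.index("Qui")] = 0.6
    src_codes = rng.choice(len(labels), size=n_seg, p=probs)
    scores = rng.normal(0.0, 1.0, size=n_seg)
    ranks = np.argsort(np.argsort(scores, kind="mergesort"), kind="mergesort")
    n_sets = config.n_conservation_sets
    base, rem = divmod(n_seg, n_sets)
    bounds = np.cumsum([base + 1 if i < rem else base for i in range(n_sets)])
    seg_set = np.searchsorted(bounds, ranks, side="right")
    profile = config.default_flip_profile()
    flip = rng.random(n_seg) < profile[seg_set]
    tgt_codes = src_codes.copy()
    shift = rng.integers(1, len(labels), size=n_seg)
    tgt_codes[flip] = (src_codes[flip] + shift[flip]) % len(labels)

    def _codes_to_seg(codes: np.ndarray, chrom: str, asm: GenomeAssembly, tissue: str) -> Segmentation:
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], change]) * b
        ends = np.concatenate([change, [n_seg]]) * b
        df = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends,
             "state": [labels[codes[s // b]] for s in starts]}
        )
        return Segmentation(tissue, df, asm, catalog, b)

    src_seg = _codes_to_seg(src_codes, "src1", src_asm, "source")
    tgt_seg = _codes_to_seg(tgt_codes, "tgt1", tgt_asm, "target")

    psize = config.ortho_pair_size
    n_pairs = L // psize
    low = rng.random(n_pairs) < config.low_identity_frac
    identity = np.where(low, rng.uniform(0.3, 0.6, n_pairs), rng.uniform(0.75, 1.0, n_pairs))
    pairs = pd.DataFrame(
        {
            "src_chrom": "src1",
            "src_start": np.arange(n_pairs) * psize,
            "src_end": (np.arange(n_pairs) + 1) * psize,
            "tgt_chrom": "tgt1",
            "tgt_start": np.arange(n_pairs) * psize,
            "tgt_end": (np.arange(n_pairs) + 1) * psize,
            "identity": np.round(identity, 4),
        }
    )
    omap = OrthologyMap(pairs)
    track = pd.DataFrame(
        {
            "chrom": "src1",
            "start": np.arange(n_seg) * b,
            "end": (np.arange(n_seg) + 1) * b,
            "score": np.round(scores, 6),
        }
    )
    seg_class = pd.DataFrame(
        {"chrom": "src1", "start": np.arange(n_seg) * b,
         "end": (np.arange(n_seg) + 1) * b, "set": seg_set}
    )
    truth = PlantedTruth(
        elements=pd.DataFrame(columns=["chrom", "start", "end", "state", "category", "tissues"]),
        flip_profile=profile,
        segment_class=seg_class,
    )
    return src_seg, tgt_seg, omap, track, truth
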