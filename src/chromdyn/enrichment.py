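"""Fold-enrichment of chromatin states in genomic features, with exact tests
and TSS-relative density profiles.

The core statistic is the base-level fold enrichment (C/A)/(B/D): C bases of
overlap between a state (A bases) and a feature (B bases) on a genome of D
bases.  Significance is assessed with a two-sided Fisher exact test on
200-bp bins, a bin counting as covered when at least half of it overlaps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FeatureSet, GeneTable, GenomeAssembly, Segmentation
from .intervals import bin_coverage, flatten, overlap_bases, total_length

__all__ = [
    "EnrichmentResult",
    "DensityProfile",
    "fold_enrichment",
    "fisher_enrichment_test",
    "tss_density_profile",
    "batch_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    state: str
    feature: str
    A: int  # state bp
    B: int  # feature bp
    C: int  # overlap bp
    D: int  # genome bp
    fold_enrichment: float  # (C/A)/(B/D); NaN when A or B is 0
    fisher_p: float | None = None


@dataclass(frozen=True)
class DensityProfile:
    state: str
    offsets: np.ndarray  # bp grid relative to TSS, upstream negative
    values: np.ndarray   # enrichment ratio per offset bin (>= 0)


def fold_enrichment(
    state_intervals: pd.DataFrame,
    feature: FeatureSet,
    assembly: GenomeAssembly,
    state: str = "state",
) -> EnrichmentResult:
    """Base-level fold enrichment (C/A)/(B/D) of a state in a feature.

    The feature is flattened to its base-union before B and C are computed.
    When A or B is zero the enrichment is NaN (undefined), never an error.
    """
    feature.check_bounds(assembly)
    A = total_length(state_intervals)
    flat_feature = flatten(feature.intervals) if not feature.intervals.empty else feature.intervals
    B = total_length(flat_feature)
    C = overlap_bases(state_intervals, flat_feature) if A and B else 0
    D = assembly.total_length
    if A == 0 or B == 0:
        fe = float("nan")
    else:
        fe = (C / A) / (B / D)
    return EnrichmentResult(state, feature.name, A, B, C, D, fe)


def _binary_bin_masks(
    intervals: pd.DataFrame, assembly: GenomeAssembly, bin_size: int
) -> np.ndarray:
    """Concatenated boolean per-bin vector: bin covered when >= 50% overlapped."""
    parts = []
    for chrom, length in assembly.chromosomes:
        cov = bin_coverage(intervals, length, chrom, bin_size)
        sizes = np.full(len(cov), bin_size, dtype=np.int64)
        if length % bin_size:
            sizes[-1] = length % bin_size
        parts.append(cov * 2 >= sizes)
    return np.concatenate(parts) if parts else np.zeros(0, dtype=bool)


def fisher_enrichment_test(
    state_intervals: pd.DataFrame,
    feature: FeatureSet,
    assembly: GenomeAssembly,
    bin_size: int = 200,
) -> float:
    """Two-sided Fisher exact p for state/feature co-occurrence over bins.

    The genome is partitioned into ``bin_size`` bins; each bin is scored as
    state-covered and/or feature-covered (>= 50% of the bin overlapped) and
    the resulting 2x2 count table is tested.  A degenerate table (any zero
    margin) returns p = 1 with a warning.
    """
    s = _binary_bin_masks(state_intervals, assembly, bin_size)
    f = _binary_bin_masks(feature.intervals, assembly, bin_size)
    a = int(np.sum(s & f))
    b = int(np.sum(s & ~f))
    c = int(np.sum(~s & f))
    d = int(np.sum(~s & ~f))
    return fisher_exact_2x2(a, b, c, d)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by the point-probability method."""
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(1.0, p))


def tss_density_profile(
    segmentation: Segmentation,
    genes: GeneTable,
    half_window: int = 20_000,
    bin_size: int | None = None,
    normalize: bool = True,
) -> dict[str, DensityProfile]:
    """State density around gene TSSs, strand-oriented, per state.

    For each offset bin on a symmetric grid around the TSS (negative =
    upstream in the gene's orientation), the value is the frequency of the
    state among all genes' bins at that offset, divided by the state's
    genome-wide bin frequency (``normalize=False`` skips the division).
    Windows running past chromosome ends are truncated: only available bins
    are counted at that offset.
    """
    bin_size = bin_size or segmentation.bin_size
    if half_window % bin_size:
        raise ValueError("half_window must be a multiple of bin_size")
    if len(genes) == 0:
        raise ValueError("no genes provided")
    codes = segmentation.bin_codes()
    labels = segmentation.catalog.labels
    n_states = len(labels)
    n_off = 2 * (half_window // bin_size)
    counts = np.zeros((n_states, n_off), dtype=np.int64)
    totals = np.zeros(n_off, dtype=np.int64)
    offsets = (np.arange(n_off) - n_off // 2) * bin_size  # left edge of each offset bin
    for _, g in genes.genes.iterrows():
        chrom = g["chrom"]
        if chrom not in segmentation.assembly:
            continue
        arr = codes[chrom]
        tss_bin = int(g["tss"]) // bin_size
        for k in range(n_off):
            rel = k - n_off // 2
            if g["strand"] == "-":
                rel = -rel - 1  # mirror: genomic right of a - strand TSS is upstream
            b = tss_bin + rel
            if 0 <= b < len(arr):
                counts[arr[b], k] += 1
                totals[k] += 1
    genome_freq = np.zeros(n_states)
    all_codes = np.concatenate([codes[c] for c, _ in segmentation.assembly.chromosomes])
    for i in range(n_states):
        genome_freq[i] = np.mean(all_codes == i)
    profiles = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        for i, lab in enumerate(labels):
            vals = freq[i]
            if normalize:
                vals = vals / genome_freq[i] if genome_freq[i] > 0 else np.zeros_like(vals)
            profiles[lab] = DensityProfile(lab, offsets.copy(), vals)
    return profiles


def batch_enrichment(
    segmentations: Mapping[str, Segmentation],
    features: Sequence[FeatureSet],
    assembly: GenomeAssembly,
    fisher: bool = False,
) -> pd.DataFrame:
    """Long-format enrichment table across tissues x states x features."""
    rows = []
    for tissue, seg in segmentations.items():
        for state in seg.catalog.labels:
            sints = seg.state_intervals(state)
            for feat in features:
                res = fold_enrichment(sints, feat, assembly, state=state)
                p = (
                    fisher_enrichment_test(sints, feat, assembly, seg.bin_size)
                    if fisher
                    else math.nan
                )
                rows.append(
                    (tissue, state, feat.name, res.A, res.B, res.C, res.D,
                     res.fold_enrichment, p)
                )
    return pd.DataFrame(
        rows,
        columns=["tissue", "state", "feature", "A", "B", "C", "D",
                 "fold_enrichment", "fisher_p"],
    )
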