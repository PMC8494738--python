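"""Tissue-specific expression and tissue-specific regulatory elements.

TSE genes: per tissue, a one-vs-rest t-statistic on column-standardized
log2(TPM+1), with tissues of the same biological sub-group excluded from the
"rest" pool; the top 5% of genes by t are the tissue's TSE set.

TSR modules: one state's regions pooled across tissues (RRAT, 1-bp merge)
carry a binary presence matrix; each region is assigned to one of 17 sharing
categories for the 14-tissue design — all-common, gut-common (the 5
intestinal tissues exactly), brain-common (the 3 brain tissues exactly) or
one of 14 tissue-specific modules — with every other presence pattern left
unassigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import fold_enrichment
from .genome import FeatureSet, GeneTable, GenomeAssembly, Segmentation
from .intervals import merge_intervals, overlap_bases

__all__ = [
    "DEFAULT_TISSUE_GROUPS",
    "INTESTINAL_TISSUES",
    "BRAIN_TISSUES",
    "DEFAULT_TISSUES",
    "ExpressionMatrix",
    "TseResult",
    "detect_tse_genes",
    "RratTable",
    "build_rrat",
    "assign_tsr_modules",
    "module_universe",
    "tse_promoter_shift",
]

INTESTINAL_TISSUES: tuple[str, ...] = ("duodenum", "jejunum", "ileum", "cecum", "colon")
BRAIN_TISSUES: tuple[str, ...] = ("cortex", "cerebellum", "hypothalamus")
SINGLETON_TISSUES: tuple[str, ...] = ("stomach", "liver", "lung", "muscle", "spleen", "adipose")
DEFAULT_TISSUES: tuple[str, ...] = INTESTINAL_TISSUES + BRAIN_TISSUES + SINGLETON_TISSUES

#: Sub-groups used when excluding related tissues from the TSE "rest" pool:
#: small intestine, large intestine, brain; all other tissues are singletons.
DEFAULT_TISSUE_GROUPS: dict[str, tuple[str, ...]] = {
    "small_intestine": ("jejunum", "ileum", "duodenum"),
    "large_intestine": ("cecum", "colon"),
    "brain": BRAIN_TISSUES,
    **{t: (t,) for t in SINGLETON_TISSUES},
}


def _group_of(tissue: str, groups: Mapping[str, Sequence[str]]) -> tuple[str, ...]:
    for members in groups.values():
        if tissue in members:
            return tuple(members)
    return (tissue,)


@dataclass
class ExpressionMatrix:
    """Gene x tissue TPM with the tissue sub-group map."""

    tpm: pd.DataFrame
    groups: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_GROUPS)
    )

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        grouped = [t for members in self.groups.values() for t in members]
        if len(grouped) != len(set(grouped)):
            raise ValueError("tissue groups must partition tissues")

    @property
    def tissues(self) -> list[str]:
        return list(self.tpm.columns)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.tpm + 1.0)


@dataclass(frozen=True)
class TseResult:
    tissue: str
    t_values: pd.Series           # per-gene t statistic, gene-id indexed
    tse_genes: tuple[str, ...]    # top-5% gene ids, best first


def detect_tse_genes(
    expr: ExpressionMatrix,
    tissue: str,
    top_fraction: float = 0.05,
    scale: str = "columns",
) -> TseResult:
    """Tissue-specific expressed genes by one-vs-rest t-statistic.

    Pipeline: log2(TPM+1); standardize each tissue column across genes to
    mean 0, variance 1 (``scale="none"`` skips this); for gene g,
    t_g = (x_gt - mean(x_g,others)) / (sd(x_g,others) * sqrt(1 + 1/n)),
    where the "others" pool excludes every tissue sharing the focal tissue's
    sub-group.  The top ceil(top_fraction * G) genes by descending t (ties
    by gene id) are the TSE set.
    """
    if tissue not in expr.tpm.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    x = expr.log2()
    if scale == "columns":
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    elif scale != "none":
        raise ValueError("scale must be 'columns' or 'none'")
    same_group = set(_group_of(tissue, expr.groups))
    others = [t for t in x.columns if t != tissue and t not in same_group]
    if len(others) < 3:
        raise ValueError("need at least 3 tissues outside the focal sub-group")
    focal = x[tissue]
    rest = x[others]
    mu = rest.mean(axis=1)
    sd = rest.std(axis=1, ddof=1)
    n = len(others)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (focal - mu) / (sd * math.sqrt(1 + 1 / n))
    # sd == 0: the rest pool is constant; the focal value either exceeds it
    # (rank first, +inf) or does not (excluded, -inf)
    t = t.where(sd > 0, np.where(focal > mu, np.inf, -np.inf))
    t.name = tissue
    k = math.ceil(top_fraction * len(t))
    ranked = t.to_frame("t").assign(gene=t.index).sort_values(
        ["t", "gene"], ascending=[False, True]
    )
    ranked = ranked[np.isfinite(ranked["t"]) | (ranked["t"] > 0)]
    tse = tuple(ranked.index[:k])
    return TseResult(tissue, t, tse)


@dataclass
class RratTable:
    """Merged regulatory regions of one state with a tissue presence matrix."""

    state: str
    regions: pd.DataFrame          # chrom, start, end (non-overlapping)
    presence: pd.DataFrame         # region index x tissue, values in {0,1}

    def __post_init__(self) -> None:
        if (self.presence.sum(axis=1) < 1).any():
            raise ValueError("every region needs at least one presence")


def build_rrat(
    segmentations: Mapping[str, Segmentation], state: str
) -> RratTable:
    """Pool one state's regions across tissues into an RRAT.

    Regions are the 1-bp-rule transitive merge of the state's intervals over
    all tissues; presence(region, tissue) = 1 iff at least one bin of the
    tissue's state overlaps the region.
    """
    per_tissue = {t: seg.state_intervals(state) for t, seg in segmentations.items()}
    non_empty = {t: df for t, df in per_tissue.items() if not df.empty}
    if not non_empty:
        raise ValueError(f"state {state!r} absent from every tissue")
    merged = merge_intervals(non_empty)
    tissues = list(segmentations)
    pres = np.zeros((len(merged), len(tissues)), dtype=np.int8)
    for j, t in enumerate(tissues):
        contrib = merged["tissues"].map(lambda tt: t in tt)
        pres[contrib.to_numpy(), j] = 1
    presence = pd.DataFrame(pres, columns=tissues)
    regions = merged[["chrom", "start", "end"]].copy()
    return RratTable(state, regions, presence)


def module_universe(
    tissues: Sequence[str] = DEFAULT_TISSUES,
    intestinal: Sequence[str] = INTESTINAL_TISSUES,
    brain: Sequence[str] = BRAIN_TISSUES,
) -> tuple[str, ...]:
    """The named sharing categories: all/gut/brain-common + one per tissue."""
    return ("all_common", "gut_common", "brain_common", *[f"{t}_specific" for t in tissues])


def assign_tsr_modules(
    rrat: RratTable,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    intestinal: Sequence[str] = INTESTINAL_TISSUES,
    brain: Sequence[str] = BRAIN_TISSUES,
) -> pd.Series:
    """Assign each RRAT region to a sharing module.

    Precedence: present in all tissues -> all_common; present in exactly the
    intestinal set -> gut_common; exactly the brain set -> brain_common;
    exactly one tissue -> that tissue's specific module; anything else ->
    "unassigned" (reported, but outside the named universe).
    """
    missing = set(tissues) - set(rrat.presence.columns)
    if missing:
        raise ValueError(f"presence matrix lacks tissues {sorted(missing)}")
    gut, brn, allset = set(intestinal), set(brain), set(tissues)
    labels = []
    for _, row in rrat.presence[list(tissues)].iterrows():
        present = {t for t in tissues if row[t]}
        if present == allset:
            labels.append("all_common")
        elif present == gut:
            labels.append("gut_common")
        elif present == brn:
            labels.append("brain_common")
        elif len(present) == 1:
            labels.append(f"{next(iter(present))}_specific")
        else:
            labels.append("unassigned")
    return pd.Series(labels, index=rrat.presence.index, name="module")


def tse_promoter_shift(
    tse: TseResult,
    segmentations: Mapping[str, Segmentation],
    genes: GeneTable,
    assembly: GenomeAssembly,
    window: int = 2000,
) -> pd.DataFrame:
    """Per-state promoter enrichment shift of TSE genes: focal minus others.

    The feature is the union of TSS +/- ``window`` regions of the TSE genes;
    each tissue's per-state fold enrichment in that feature is computed and
    the shift is FE(focal) - mean(FE over the other tissues).
    """
    if not tse.tse_genes:
        raise ValueError("empty TSE gene set")
    known = set(genes.genes["gene_id"])
    missing = [g for g in tse.tse_genes if g not in known]
    if missing:
        raise ValueError(f"TSE genes missing from gene table: {missing[:5]}")
    windows = genes.tss_windows(window, assembly, ids=tse.tse_genes)
    feature = FeatureSet(f"TSE_{tse.tissue}_promoters", windows)
    labels = next(iter(segmentations.values())).catalog.labels
    fe = pd.DataFrame(index=list(labels), columns=list(segmentations), dtype=float)
    for t, seg in segmentations.items():
        for state in labels:
            fe.loc[state, t] = fold_enrichment(
                seg.state_intervals(state), feature, assembly, state=state
            ).fold_enrichment
    others = [t for t in fe.columns if t != tse.tissue]
    shift = fe[tse.tissue] - fe[others].mean(axis=1)
    return pd.DataFrame(
        {"fe_focal": fe[tse.tissue], "fe_others_mean": fe[others].mean(axis=1), "shift": shift}
    )
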