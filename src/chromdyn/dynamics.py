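"""Genome-wide chromatin-state dynamics across tissues.

Covers four analyses: (i) clustering of 2-Mb genome fragments into modules
by their average state-frequency composition; (ii) cumulative-coverage
variability curves per state (aGL/TGL); (iii) inter-tissue state switching
probabilities (Obe/TbAe on the shared bin grid); and (iv) hierarchical
clustering of epigenomes from Poisson signal-confidence scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

from .genome import Segmentation
from .intervals import flatten, merge_intervals, overlap_bases, total_length

__all__ = [
    "fragment_state_matrix",
    "cluster_fragments",
    "module_contrast_test",
    "VariabilityCurve",
    "variability_curve",
    "switching_probability",
    "pair_switch_matrix",
    "poisson_signal_score",
    "cluster_epigenomes",
]


def fragment_state_matrix(
    segmentations: Mapping[str, Segmentation],
    fragments: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """State-frequency composition of each genome fragment.

    For each tissue, the frequency of each state inside a fragment is its
    bin count divided by the fragment's total bins; entries are then averaged
    across tissues.  Returns (average matrix states x fragments, per-tissue
    matrices for audit).  Columns are probability vectors (sum to 1).
    """
    segs = list(segmentations.values())
    catalog = segs[0].catalog
    labels = list(catalog.labels)
    assembly = segs[0].assembly
    for _, r in fragments.iterrows():
        if r["chrom"] not in assembly or r["end"] > assembly.length_of(r["chrom"]):
            raise ValueError(f"fragment {tuple(r[:3])} outside assembly")
    per_tissue: dict[str, pd.DataFrame] = {}
    for tissue, seg in segmentations.items():
        codes = seg.bin_codes()
        b = seg.bin_size
        mat = np.zeros((len(labels), len(fragments)))
        for j, (_, r) in enumerate(fragments.iterrows()):
            arr = codes[r["chrom"]][r["start"] // b : r["end"] // b]
            cnt = np.bincount(arr, minlength=len(labels))
            mat[:, j] = cnt / cnt.sum()
        per_tissue[tissue] = pd.DataFrame(mat, index=labels, columns=fragments["index"])
    avg = sum(per_tissue.values()) / len(per_tissue)
    return avg, per_tissue


@dataclass(frozen=True)
class ModuleAssignment:
    fragment_module: pd.Series  # fragment index -> module label "M1".."Mk"
    state_cluster: pd.Series    # state label -> row-cluster id
    counts: pd.Series           # fragments per module


def cluster_fragments(
    matrix: pd.DataFrame,
    k: int = 12,
    seed: int = 0,
    n_init: int = 25,
    row_k: int = 3,
) -> ModuleAssignment:
    """K-means the fragments (columns) into k modules; states (rows) into row_k.

    Euclidean metric in state-frequency space, best of ``n_init`` seeded
    restarts by within-cluster sum of squares; deterministic given the seed.
    """
    if matrix.empty:
        raise ValueError("empty fragment-state matrix")
    if k < 1 or k > matrix.shape[1]:
        raise ValueError("k must be in [1, n_fragments]")
    X = matrix.to_numpy().T
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    modules = pd.Series(
        [f"M{c + 1}" for c in km.labels_], index=matrix.columns, name="module"
    )
    rk = min(row_k, matrix.shape[0])
    km_rows = KMeans(n_clusters=rk, n_init=n_init, random_state=seed).fit(matrix.to_numpy())
    state_cluster = pd.Series(km_rows.labels_, index=matrix.index, name="state_cluster")
    return ModuleAssignment(modules, state_cluster, modules.value_counts())


def module_contrast_test(
    assignment: ModuleAssignment,
    fragment_values: pd.Series,
    reference_module: str = "M3",
) -> pd.DataFrame:
    """Welch two-sided t of each module's fragment values vs a reference module.

    ``fragment_values`` maps fragment index to a scalar (mean expression or
    mean methylation of the fragment).  No multiple-testing adjustment is
    applied.  Modules with fewer than 2 fragments get NaN statistics.
    """
    mod = assignment.fragment_module
    ref_vals = fragment_values[mod[mod == reference_module].index].dropna()
    if ref_vals.empty:
        raise ValueError(f"reference module {reference_module!r} is empty")
    rows = []
    for m in sorted(mod.unique(), key=lambda s: int(s[1:])):
        if m == reference_module:
            continue
        vals = fragment_values[mod[mod == m].index].dropna()
        if len(vals) < 2 or len(ref_vals) < 2:
            rows.append((m, len(vals), np.nan, np.nan))
            continue
        if vals.std(ddof=1) == 0 and ref_vals.std(ddof=1) == 0:
            t = 0.0 if vals.mean() == ref_vals.mean() else np.inf * np.sign(vals.mean() - ref_vals.mean())
            p = 1.0 if t == 0.0 else 0.0
        else:
            t, p = stats.ttest_ind(vals, ref_vals, equal_var=False)
        rows.append((m, len(vals), float(t), float(p)))
    return pd.DataFrame(rows, columns=["module", "n_fragments", "t", "p"])


@dataclass(frozen=True)
class VariabilityCurve:
    state: str
    tissues: tuple[str, ...]      # order of accumulation (decreasing GL/TGL)
    values: np.ndarray            # cumulative aGL/TGL after each tissue
    gl: dict[str, int]            # per-tissue state bp
    tgl: int                      # union bp across tissues


def variability_curve(
    state: str, segmentations: Mapping[str, Segmentation]
) -> VariabilityCurve:
    """Cumulative genome-coverage fraction curve of a state across tissues.

    GL_t is the state's bp in tissue t; TGL is the bp of the pooled regions
    across all tissues (1-bp merge).  Tissues are added in decreasing
    GL_t/TGL order (ties alphabetical) and the curve records the union bp so
    far over TGL: non-decreasing, ending at 1.  Fast-rising curves mean a
    constitutive (shared) state; slow-rising curves a variable one.
    """
    per_tissue = {t: seg.state_intervals(state) for t, seg in segmentations.items()}
    per_tissue = {t: df for t, df in per_tissue.items() if not df.empty}
    if not per_tissue:
        return VariabilityCurve(state, (), np.array([]), {}, 0)
    rrat = merge_intervals(per_tissue)
    tgl = int((rrat["end"] - rrat["start"]).sum())
    gl = {t: total_length(df) for t, df in per_tissue.items()}
    order = sorted(gl, key=lambda t: (-gl[t], t))
    acc = None
    values = []
    for t in order:
        acc = per_tissue[t] if acc is None else pd.concat([acc, per_tissue[t]])
        acc = flatten(acc)
        values.append(total_length(acc) / tgl)
    return VariabilityCurve(state, tuple(order), np.asarray(values), gl, tgl)


def switching_probability(
    state: str, seg_a: Segmentation, seg_b: Segmentation
) -> tuple[float, float, float]:
    """State retention between two tissues on the shared bin grid.

    TbAe = bins of state e in tissue A; Obe = bins carrying e in both A and
    B.  P(A->B) = Obe/TbAe, P(B->A) = Obe/TbBe; the pair value is their
    mean.  These are retention probabilities: 1 - retention is the state
    mass switching away.  A direction with zero state bins is NaN.
    """
    if seg_a.bin_size != seg_b.bin_size:
        raise ValueError("segmentations must share a bin grid")
    b = seg_a.bin_size
    ia, ib = seg_a.state_intervals(state), seg_b.state_intervals(state)
    tb_a = total_length(ia) // b
    tb_b = total_length(ib) // b
    ob = overlap_bases(ia, ib) // b
    p_ab = ob / tb_a if tb_a else float("nan")
    p_ba = ob / tb_b if tb_b else float("nan")
    pair = np.nanmean([p_ab, p_ba]) if (tb_a or tb_b) else float("nan")
    return p_ab, p_ba, float(pair)


def pair_switch_matrix(
    state: str, segmentations: Mapping[str, Segmentation]
) -> pd.DataFrame:
    """Symmetric tissue x tissue matrix of pair switching probabilities."""
    tissues = list(segmentations)
    mat = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    for i, ta in enumerate(tissues):
        if total_length(segmentations[ta].state_intervals(state)) == 0:
            mat.loc[ta, ta] = np.nan
        for tb in tissues[i + 1 :]:
            _, _, pair = switching_probability(state, segmentations[ta], segmentations[tb])
            mat.loc[ta, tb] = mat.loc[tb, ta] = pair
    return mat


def poisson_signal_score(count, lam: float):
    """Signal confidence score -log10 P(X >= count) for X ~ Poisson(lam).

    The upper tail is inclusive; count 0 scores 0 exactly.  Vectorized over
    ``count``.
    """
    if lam <= 0:
        raise ValueError("background lambda must be positive")
    count = np.asarray(count)
    if (count < 0).any():
        raise ValueError("counts must be non-negative")
    # P(X >= k) = sf(k-1); use logsf for numerical range
    score = -stats.poisson.logsf(count - 1, lam) / np.log(10)
    return float(score) if score.ndim == 0 else score


def cluster_epigenomes(score_matrix: pd.DataFrame) -> pd.DataFrame:
    """Hierarchical Ward-D2/Euclidean clustering of samples by region scores.

    ``score_matrix`` is samples x regions (signal confidence scores on one
    state's pooled regions).  Samples are pre-sorted by id so the result is
    invariant to input row order.  Returns the linkage as a table
    (node_a, node_b, height, size) in scipy convention, with leaf ids being
    positions in the sorted sample list (also returned via attrs).
    """
    if score_matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = score_matrix.sort_index()
    if np.allclose(X.to_numpy().std(axis=0), 0):
        warnings.warn("constant score matrix; all distances zero")
    Z = linkage(X.to_numpy(), method="ward")  # Ward-D2 on observations
    out = pd.DataFrame(Z, columns=["node_a", "node_b", "height", "size"])
    out.attrs["samples"] = list(X.index)
    return out
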