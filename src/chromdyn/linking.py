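"""CTCF-loop construction from motif hits and within-loop enhancer-gene
linking by Spearman rank correlation with BH FDR control.

Loops are predicted from convergently oriented CTCF motif occurrences: each
forward-strand hit pairs with its nearest downstream reverse-strand hit
within a span cap, and nested or overlapping candidate spans are merged into
their union.  Every (enhancer, gene-TSS) pair co-resident in a loop is then
scored by the Spearman correlation of enhancer signal and gene expression
across tissues; BH is applied once across all loops.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .specificity import ExpressionMatrix

__all__ = [
    "MotifHit",
    "CtcfLoop",
    "scan_pwm",
    "build_loops",
    "spearman_p",
    "link_enhancers",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float


@dataclass(frozen=True)
class CtcfLoop:
    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int

    @property
    def span(self) -> tuple[int, int]:
        return self.left_start, self.right_end

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.left_start <= pos < self.right_end


def _logodds(pwm: np.ndarray, background: float = 0.25, pseudo: float = 1e-9) -> np.ndarray:
    return np.log2((pwm + pseudo) / background)


def scan_pwm(
    sequence: str,
    pwm: np.ndarray,
    threshold: float,
    chrom: str = "chr1",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of a sequence with a position weight matrix.

    ``pwm`` is a (motif_length x 4) matrix of base probabilities (columns
    A,C,G,T; each position sums to 1).  Scores are log-odds against a uniform
    background; a hit is reported where the score reaches ``threshold``.
    Coordinates are half-open on the forward strand regardless of hit strand.
    """
    seq = sequence.upper()
    w = pwm.shape[0]
    if pwm.shape[1] != 4 or not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pwm must be (length x 4) with rows summing to 1")
    if len(seq) < w:
        raise ValueError("sequence shorter than motif")
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    lo = _logodds(pwm)
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(_ALPHABET):
        lut[ord(b)] = i
    codes = lut[idx]
    hits: list[MotifHit] = []
    n = len(seq) - w + 1
    pos_scores = np.zeros(n)
    for j in range(w):
        pos_scores += lo[j, codes[j : j + n]]
    # reverse strand: score of the reverse-complement motif on the forward text
    lo_rc = lo[::-1, ::-1]
    neg_scores = np.zeros(n)
    for j in range(w):
        neg_scores += lo_rc[j, codes[j : j + n]]
    for i in range(n):
        if pos_scores[i] >= threshold:
            hits.append(MotifHit(chrom, offset + i, offset + i + w, "+", float(pos_scores[i])))
        if neg_scores[i] >= threshold:
            hits.append(MotifHit(chrom, offset + i, offset + i + w, "-", float(neg_scores[i])))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def build_loops(hits: list[MotifHit], max_span: int = 1_000_000) -> list[CtcfLoop]:
    """Predict loops from convergent motif pairs, then merge candidate spans.

    Each + hit pairs with the nearest downstream - hit whose span stays
    within ``max_span``; nested or overlapping candidate spans on a
    chromosome are merged into their union, so returned loops are pairwise
    disjoint.  Merged loops keep the outermost anchors.
    """
    loops: list[CtcfLoop] = []
    for chrom in sorted({h.chrom for h in hits}):
        ch = sorted([h for h in hits if h.chrom == chrom], key=lambda h: h.start)
        fwd = [h for h in ch if h.strand == "+"]
        rev = [h for h in ch if h.strand == "-"]
        candidates = []
        for f in fwd:
            partners = [r for r in rev if r.start >= f.end and r.end - f.start <= max_span]
            if partners:
                r = min(partners, key=lambda h: h.start)
                candidates.append((f, r))
        if not candidates:
            continue
        candidates.sort(key=lambda fr: fr[0].start)
        cur: list[tuple[MotifHit, MotifHit]] = [candidates[0]]

        def _flush(group):
            left = min(f.start for f, _ in group)
            left_end = min(f.end for f, _ in group)
            right_end = max(r.end for _, r in group)
            right_start = max(r.start for _, r in group)
            loops.append(CtcfLoop(chrom, left, left_end, right_start, right_end))

        span_end = candidates[0][1].end
        for f, r in candidates[1:]:
            if f.start < span_end:  # overlapping or nested candidate spans
                cur.append((f, r))
                span_end = max(span_end, r.end)
            else:
                _flush(cur)
                cur = [(f, r)]
                span_end = r.end
        _flush(cur)
    return loops


@lru_cache(maxsize=16)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted Spearman rho values over all permutations of n untied ranks."""
    base = np.arange(n, dtype=float)
    rhos = []
    denom = n * (n * n - 1) / 6.0
    for perm in itertools.permutations(range(n)):
        d2 = np.sum((base - np.asarray(perm, dtype=float)) ** 2)
        rhos.append(1.0 - d2 / denom)
    return np.sort(np.asarray(rhos))


def spearman_p(rho: float, n: int, exact_max_n: int = 9) -> float:
    """Two-sided p for a Spearman rho at sample size n.

    Exact permutation null (full enumeration, untied ranks) for n <=
    ``exact_max_n``; t-distribution approximation above.
    """
    if n < 3:
        return 1.0
    if abs(rho) >= 1.0 - 1e-12:
        if n <= exact_max_n:
            null = _exact_rho_null(n)
            return float(np.mean(np.abs(null) >= 1.0 - 1e-12))
        rho = math.copysign(1.0 - 1e-12, rho)
    if n <= exact_max_n:
        null = _exact_rho_null(n)
        return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def link_enhancers(
    loops: list[CtcfLoop],
    enhancer_signal: pd.DataFrame,
    expr: ExpressionMatrix,
    gene_tss: pd.DataFrame,
    alpha: float = 0.05,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Call enhancer-gene pairs inside loops by rank correlation at FDR alpha.

    ``enhancer_signal`` is element x tissue (rows indexed by enhancer id,
    with per-element coordinates in columns chrom/start/end or supplied via
    ``attrs['coords']``); ``gene_tss`` maps gene_id to (chrom, tss).  For
    every enhancer (midpoint) and gene TSS co-resident in one merged loop,
    the Spearman correlation across shared tissues is computed;
    Benjamini-Hochberg is applied once over all tested pairs and pairs with
    q < alpha are returned (``positive_only`` restricts to rho > 0).
    """
    coord_cols = ["chrom", "start", "end"]
    coords = enhancer_signal[coord_cols]
    sig = enhancer_signal.drop(columns=coord_cols)
    tissues = [t for t in sig.columns if t in expr.tpm.columns]
    if len(tissues) < 5:
        raise ValueError("need at least 5 shared tissues for rank correlation")
    n = len(tissues)
    records = []
    skipped = []
    for loop in loops:
        mid = (coords["start"] + coords["end"]) // 2
        enh_in = coords.index[
            (coords["chrom"] == loop.chrom)
            & (mid >= loop.left_start)
            & (mid < loop.right_end)
        ]
        genes_in = gene_tss.index[
            (gene_tss["chrom"] == loop.chrom)
            & (gene_tss["tss"] >= loop.left_start)
            & (gene_tss["tss"] < loop.right_end)
        ]
        for e in enh_in:
            svec = sig.loc[e, tissues].astype(float)
            for g in genes_in:
                if g not in expr.tpm.index:
                    continue
                evec = expr.tpm.loc[g, tissues].astype(float)
                if svec.nunique() < 2 or evec.nunique() < 2:
                    skipped.append((e, g, "constant row"))
                    continue
                rho = stats.spearmanr(svec, evec).statistic
                p = spearman_p(float(rho), n)
                records.append((e, g, loop.chrom, loop.left_start, loop.right_end, rho, p))
    out = pd.DataFrame(
        records,
        columns=["enhancer", "gene", "chrom", "loop_start", "loop_end", "rho", "p"],
    )
    out.attrs["skipped"] = skipped
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    keep = out["q"] < alpha
    if positive_only:
        keep &= out["rho"] > 0
    return out[keep].sort_values("q").reset_index(drop=True)
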