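"""Monte-Carlo calibration of the pipeline's statistical procedures.

These drivers measure operating characteristics on synthetic data: the
type-I error and power of the cyclical permutation test, and the realized
family-wise false-link rate of BH-controlled enhancer-gene linking on
all-decoy loops.  They are used by the test suite and the reproduction
script; sizes are scaled so a full run stays in the tens of seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .linking import CtcfLoop, link_enhancers
from .selection import cyclical_permutation_test
from .specificity import ExpressionMatrix

__all__ = [
    "permutation_rejection_rate",
    "link_false_discovery_calibration",
    "tse_recovery",
]


def _grid_snps(rng: np.random.Generator, n_snps: int, inflation: float,
               member_frac: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    stat = rng.chisquare(1, n_snps)
    pos = np.arange(n_snps) * 1000 + 500
    m = int(round(member_frac * n_snps))
    start = int(rng.integers(0, n_snps - m))
    stat[start : start + m] *= inflation
    ann = pd.DataFrame(
        {"chrom": ["chr1"], "start": [pos[start] - 1], "end": [pos[start + m - 1] + 1]}
    )
    return pd.DataFrame({"chrom": "chr1", "pos": pos, "stat": stat}), ann


def permutation_rejection_rate(
    n_seeds: int,
    inflation: float = 1.0,
    n_snps: int = 500,
    member_frac: float = 0.10,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of synthetic cohorts where the permutation test rejects.

    With ``inflation=1`` this estimates the type-I error at level alpha
    (annotation placement is random, statistics are null chi-square); with
    inflation > 1 it estimates power against a planted enrichment.
    """
    root = np.random.SeedSequence(seed, spawn_key=(100,))
    rejections = 0
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)
        snps, ann = _grid_snps(rng, n_snps, inflation, member_frac)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = cyclical_permutation_test(snps, ann, n_perm=n_perm, seed=sub_seed)
        rejections += res.p <= alpha
    return rejections / n_seeds


def link_false_discovery_calibration(
    n_seeds: int = 200,
    n_decoys: int = 10,
    n_genes: int = 5,
    n_tissues: int = 14,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """All-decoy linking: how often BH at level alpha calls any false link.

    Each cohort holds one loop with ``n_decoys`` enhancers whose signal is
    independent noise and ``n_genes`` resident genes; every called pair is a
    false discovery.  Returns the fraction of cohorts with at least one
    false link (the family-wise realization of the FDR level under the
    global null) and the per-test rejection fraction.
    """
    root = np.random.SeedSequence(seed, spawn_key=(101,))
    tissues = [f"t{i}" for i in range(n_tissues)]
    loops = [CtcfLoop("chr1", 0, 19, 99_981, 100_000)]
    any_link = 0
    n_links = 0
    n_tests = 0
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)
        gene_ids = [f"g{i}" for i in range(n_genes)]
        expr = ExpressionMatrix(
            pd.DataFrame(rng.lognormal(1, 1, (n_genes, n_tissues)),
                         index=gene_ids, columns=tissues),
            groups={t: (t,) for t in tissues},
        )
        gene_tss = pd.DataFrame(
            {"chrom": "chr1", "tss": 10_000 + 5_000 * np.arange(n_genes)}, index=gene_ids
        )
        rows = []
        for d in range(n_decoys):
            rows.append(["chr1", 30_000 + 400 * d, 30_400 + 400 * d,
                         *rng.normal(5, 1, n_tissues)])
        sig = pd.DataFrame(rows, index=[f"e{d}" for d in range(n_decoys)],
                           columns=["chrom", "start", "end", *tissues])
        out = link_enhancers(loops, sig, expr, gene_tss, alpha=alpha)
        any_link += int(len(out) > 0)
        n_links += len(out)
        n_tests += n_decoys * n_genes
    return {
        "family_rejection_rate": any_link / n_seeds,
        "per_test_rejection_rate": n_links / n_tests,
    }


def tse_recovery(config=None) -> float:
    """Fraction of planted tissue-specific genes recovered in the top 5%."""
    from .simulate import PlantedTruth, SimulationConfig, simulate_expression
    from .specificity import detect_tse_genes

    config = config or SimulationConfig()
    truth = PlantedTruth(elements=pd.DataFrame())
    expr = simulate_expression(config, truth)
    hit = total = 0
    for t, planted in truth.tse_genes.items():
        res = detect_tse_genes(expr, t)
        hit += len(set(planted) & set(res.tse_genes))
        total += len(planted)
    return hit / total
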