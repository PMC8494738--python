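import numpy as np
import pandas as pd
import pytest

from chromdyn.genome import GenomeAssembly, Segmentation, StateCatalog
from chromdyn.simulate import SimulationConfig


def iv(*rows):
    """Shorthand interval table: iv(("chrA", 0, 100), ...)."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.fixture(scope="session")
def toy_assembly():
    return GenomeAssembly("toy", (("chrA", 10_000), ("chrB", 6_000)))


@pytest.fixture(scope="session")
def catalog():
    return StateCatalog()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same 14-tissue design on a 2-Mb genome."""
    return SimulationConfig(
        seed=7,
        chrom_lengths=(("chrA", 1_200_000), ("chrB", 800_000)),
        n_all_common=10,
        n_gut_common=10,
        n_brain_common=10,
        n_specific_per_tissue=2,
        n_background=30,
        n_genes=200,
        n_tse_per_tissue=3,
        n_snps=1000,
        snp_spacing=1000,
        n_loops=4,
        loop_span=80_000,
    )


def make_segmentation(assembly, rows, tissue="t1", catalog=None):
    """Build a full partition from labelled rows, filling gaps with Qui."""
    catalog = catalog or StateCatalog()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    full = []
    for chrom, length in assembly.chromosomes:
        sub = df[df["chrom"] == chrom].sort_values("start")
        pos = 0
        for s, e, st in zip(sub["start"], sub["end"], sub["state"]):
            if s > pos:
                full.append((chrom, pos, s, "Qui"))
            full.append((chrom, s, e, st))
            pos = e
        if pos < length:
            full.append((chrom, pos, length, "Qui"))
    return Segmentation(
        tissue, pd.DataFrame(full, columns=["chrom", "start", "end", "state"]),
        assembly, catalog,
    )


def brute_force_overlap(a: pd.DataFrame, b: pd.DataFrame, genome_size=100_000) -> int:
    """Per-base oracle for overlap_bases on toy genomes."""
    total = 0
    for chrom in set(a["chrom"]) | set(b["chrom"]):
        mask_a = np.zeros(genome_size, dtype=bool)
        mask_b = np.zeros(genome_size, dtype=bool)
        for _, r in a[a["chrom"] == chrom].iterrows():
            mask_a[r["start"]:r["end"]] = True
        for _, r in b[b["chrom"] == chrom].iterrows():
            mask_b[r["start"]:r["end"]] = True
        total += int(np.sum(mask_a & mask_b))
    return total
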