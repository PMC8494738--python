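"""Domain types for genome assemblies, chromatin-state segmentations and gene tables.

Coordinates are 0-based half-open (BED convention) throughout the package;
GFF/GTF input is converted on read.  A segmentation is a labelled partition of
the genome into state intervals aligned to a fixed bin grid (200 bp by
default), with quiescent state filling every gap, mirroring the dense-BED
output of hidden-Markov chromatin-state segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "StateCatalog",
    "Segmentation",
    "FeatureSet",
    "GeneTable",
    "DEFAULT_STATES",
    "DEFAULT_STATE_GROUPS",
    "tile_genome",
    "DEFAULT_CHROM_ALLOWLIST",
]

#: The 15-label chromatin-state vocabulary: active/heterochromatic/bivalent
#: promoters, TSS-flanking transcribed states, five enhancer flavours, an
#: accessible-but-unmarked state, two Polycomb-repressed states and quiescent.
DEFAULT_STATES: tuple[str, ...] = (
    "TssA", "TssAHet", "TxFlnk", "TxFlnkWk", "TxFlnkHet",
    "EnhA", "EnhAMe", "EnhAWk", "EnhAHet", "EnhPois",
    "ATAC_Is", "TssBiv", "Repr", "ReprWk", "Qui",
)

DEFAULT_STATE_GROUPS: dict[str, str] = {
    "TssA": "promoter", "TssAHet": "promoter", "TssBiv": "promoter",
    "TxFlnk": "transcribed", "TxFlnkWk": "transcribed", "TxFlnkHet": "transcribed",
    "EnhA": "enhancer", "EnhAMe": "enhancer", "EnhAWk": "enhancer",
    "EnhAHet": "enhancer", "EnhPois": "enhancer",
    "ATAC_Is": "accessible",
    "Repr": "repressed", "ReprWk": "repressed",
    "Qui": "quiescent",
}

#: Chromosome names eligible for genome-wide tiling (autosomes + sex
#: chromosomes, with or without a "chr" prefix); unplaced scaffolds/contigs
#: fall outside this list and are excluded.
DEFAULT_CHROM_ALLOWLIST: frozenset[str] = frozenset(
    [str(i) for i in range(1, 40)] + ["X", "Y"]
    + [f"chr{i}" for i in range(1, 40)] + ["chrX", "chrY"]
)


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered set of named chromosomes with lengths in bp."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for c, length in self.chromosomes:
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {length!r}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return int(sum(l for _, l in self.chromosomes))

    def length_of(self, chrom: str) -> int:
        for c, l in self.chromosomes:
            if c == chrom:
                return int(l)
        raise KeyError(f"unknown chromosome {chrom!r}")

    def chrom_order(self) -> dict[str, int]:
        return {c: i for i, (c, _) in enumerate(self.chromosomes)}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_order()


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class StateCatalog:
    """Ordered chromatin-state labels plus a functional group per label."""

    labels: tuple[str, ...] = DEFAULT_STATES
    groups: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_STATE_GROUPS))
    quiescent: str = "Qui"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("state labels must be unique")
        if self.quiescent not in self.labels:
            raise ValueError("quiescent label must be in the catalog")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)


def _interval_frame(df: pd.DataFrame, extra: Sequence[str] = ()) -> pd.DataFrame:
    cols = ["chrom", "start", "end", *extra]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"interval table missing columns {missing}")
    out = df[cols].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] < 0).any() or (out["end"] <= out["start"]).any():
        raise ValueError("intervals must satisfy 0 <= start < end")
    return out.reset_index(drop=True)


@dataclass
class Segmentation:
    """One tissue's genome-wide chromatin-state partition.

    ``intervals`` is a table (chrom, start, end, state) of non-overlapping
    intervals that together cover every chromosome of ``assembly`` exactly
    once, with boundaries on the ``bin_size`` grid (the final bin of a
    chromosome may be short).
    """

    tissue: str
    intervals: pd.DataFrame
    assembly: GenomeAssembly
    catalog: StateCatalog = field(default_factory=StateCatalog)
    bin_size: int = 200

    def __post_init__(self) -> None:
        self.intervals = _interval_frame(self.intervals, ["state"])
        order = self.assembly.chrom_order()
        unknown_chrom = set(self.intervals["chrom"]) - set(order)
        if unknown_chrom:
            raise ValueError(f"intervals on unknown chromosomes {sorted(unknown_chrom)}")
        unknown_state = set(self.intervals["state"]) - set(self.catalog.labels)
        if unknown_state:
            raise KeyError(f"unknown state labels {sorted(unknown_state)}")
        self.intervals = self.intervals.sort_values(
            ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
        ).reset_index(drop=True)
        self._validate_partition()

    def _validate_partition(self) -> None:
        for chrom, length in self.assembly.chromosomes:
            sub = self.intervals[self.intervals["chrom"] == chrom]
            if sub.empty:
                raise ValueError(f"chromosome {chrom} not covered")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != length:
                raise ValueError(f"chromosome {chrom} not fully covered")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(f"gaps or overlaps on chromosome {chrom}")
            interior = np.concatenate([starts, ends[:-1]])
            if (interior % self.bin_size).any():
                raise ValueError(f"boundaries off the {self.bin_size}-bp grid on {chrom}")

    def state_intervals(self, state: str) -> pd.DataFrame:
        """Intervals of one state as a (chrom, start, end) table."""
        if state not in self.catalog:
            raise KeyError(f"unknown state label {state!r}")
        sub = self.intervals[self.intervals["state"] == state]
        return sub[["chrom", "start", "end"]].reset_index(drop=True)

    def state_coverage(self) -> pd.Series:
        """Total bp per state, indexed by catalog order (zeros included)."""
        lengths = self.intervals["end"] - self.intervals["start"]
        cov = lengths.groupby(self.intervals["state"]).sum()
        return cov.reindex(self.catalog.labels, fill_value=0).astype(np.int64)

    def bin_codes(self) -> dict[str, np.ndarray]:
        """Per-chromosome array of state indices, one entry per bin."""
        codes: dict[str, np.ndarray] = {}
        state_idx = {s: i for i, s in enumerate(self.catalog.labels)}
        b = self.bin_size
        for chrom, length in self.assembly.chromosomes:
            n_bins = -(-length // b)
            arr = np.empty(n_bins, dtype=np.int16)
            sub = self.intervals[self.intervals["chrom"] == chrom]
            for start, end, state in zip(sub["start"], sub["end"], sub["state"]):
                arr[start // b : -(-end // b)] = state_idx[state]
            codes[chrom] = arr
        return codes


@dataclass
class FeatureSet:
    """A named set of genomic intervals (exons, CpG islands, TSS windows...).

    Intervals may overlap; base-level statistics flatten them first.
    """

    name: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        self.intervals = _interval_frame(self.intervals)

    def check_bounds(self, assembly: GenomeAssembly) -> None:
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            if chrom not in assembly:
                raise ValueError(f"feature {self.name!r} on unknown chromosome {chrom}")
            if (sub["end"] > assembly.length_of(chrom)).any():
                raise ValueError(f"feature {self.name!r} exceeds {chrom} bounds")


@dataclass
class GeneTable:
    """Gene annotations reduced to the fields the analyses need.

    ``genes`` columns: gene_id, chrom, strand, tss, tes, biotype.  On the +
    strand the TSS is the interval start; on the - strand it is the end.
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "strand", "tss", "tes", "biotype"]
        missing = [c for c in required if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        self.genes = self.genes.reset_index(drop=True)

    def tss_windows(self, half: int, assembly: GenomeAssembly,
                    ids: Iterable[str] | None = None) -> pd.DataFrame:
        """TSS +/- ``half`` bp windows clipped to chromosome ends."""
        g = self.genes if ids is None else self.genes[self.genes["gene_id"].isin(set(ids))]
        rows = []
        for _, r in g.iterrows():
            length = assembly.length_of(r["chrom"])
            start = max(0, int(r["tss"]) - half)
            end = min(length, int(r["tss"]) + half)
            if end > start:
                rows.append((r["chrom"], start, end))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def __len__(self) -> int:
        return len(self.genes)


def tile_genome(
    assembly: GenomeAssembly,
    tile: int = 2_000_000,
    allowlist: Iterable[str] | None = DEFAULT_CHROM_ALLOWLIST,
    keep_remainder: bool = False,
) -> pd.DataFrame:
    """Tile the genome into fixed-size fragments.

    Per chromosome, ``floor(length / tile)`` full tiles are laid from
    position 0; the terminal sub-tile remainder is dropped unless
    ``keep_remainder`` is set.  Chromosomes outside ``allowlist`` (contigs,
    unplaced scaffolds) are excluded; pass ``allowlist=None`` to tile all.

    Returns a table (chrom, start, end, index) with a genome-wide running
    fragment index.
    """
    if tile <= 0:
        raise ValueError("tile size must be positive")
    allow = None if allowlist is None else set(allowlist)
    rows = []
    for chrom, length in assembly.chromosomes:
        if allow is not None and chrom not in allow:
            continue
        n_full = length // tile
        for i in range(n_full):
            rows.append((chrom, i * tile, (i + 1) * tile))
        if keep_remainder and length % tile:
            rows.append((chrom, n_full * tile, length))
    if not rows:
        import warnings

        warnings.warn("tile size exceeds every chromosome; no fragments produced")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["index"] = np.arange(len(df), dtype=np.int64)
    return df
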