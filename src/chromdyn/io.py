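"""Readers and writers for the plain-text formats the pipeline touches.

BED (3/4/6 columns), chrom.sizes, bedGraph and GFF3/GTF gene rows.  Writers
are deterministic: rows sorted by assembly chromosome order then start.
"""

from __future__ import annotations

import os
from importlib import resources
from typing import IO

import numpy as np
import pandas as pd

from .genome import GeneTable, GenomeAssembly, Segmentation, StateCatalog

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_segmentation",
    "write_segmentation",
    "read_bedgraph",
    "read_gene_table",
    "bundled_path",
    "load_susscr11_assembly",
]

PathLike = str | os.PathLike


def read_chrom_sizes(path: PathLike, name: str | None = None) -> GenomeAssembly:
    """Read a two-column chrom.sizes table into an assembly.

    Row order is preserved; duplicate names, non-integer or non-positive
    lengths, and empty files are errors.
    """
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            chrom, raw = parts
            if chrom in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            try:
                length = int(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer length {raw!r}") from None
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length {length}")
            seen.add(chrom)
            chroms.append((chrom, length))
    if not chroms:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeAssembly(name or os.path.basename(str(path)), tuple(chroms))


def read_bed(path: PathLike) -> pd.DataFrame:
    """Read BED3/4/6 into a table; extra columns become name/score/strand."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def _sort_for_write(df: pd.DataFrame, assembly: GenomeAssembly | None) -> pd.DataFrame:
    if assembly is not None:
        order = assembly.chrom_order()
        key = df["chrom"].map(order)
    else:
        key = df["chrom"]
    return df.assign(_k=key).sort_values(["_k", "start"]).drop(columns="_k")


def write_bed(df: pd.DataFrame, path: PathLike, assembly: GenomeAssembly | None = None) -> None:
    out = _sort_for_write(df, assembly)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_segmentation(
    path: PathLike | IO[str],
    catalog: StateCatalog,
    assembly: GenomeAssembly,
    tissue: str | None = None,
    bin_size: int = 200,
) -> Segmentation:
    """Read a 4-column dense segmentation BED.

    Gaps are filled with the quiescent state and adjacent same-label rows are
    merged, so the result is a full partition of the assembly.  Unknown
    labels, intervals past chromosome ends and overlapping rows are errors.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "state"],
                     usecols=[0, 1, 2, 3])
    unknown = set(df["state"]) - set(catalog.labels)
    if unknown:
        raise KeyError(f"unknown state labels {sorted(unknown)}")
    order = assembly.chrom_order()
    bad_chrom = set(df["chrom"]) - set(order)
    if bad_chrom:
        raise ValueError(f"unknown chromosomes {sorted(bad_chrom)}")
    rows: list[tuple[str, int, int, str]] = []
    qui = catalog.quiescent
    for chrom, length in assembly.chromosomes:
        sub = df[df["chrom"] == chrom].sort_values("start")
        pos = 0
        for s, e, lab in zip(sub["start"], sub["end"], sub["state"]):
            s, e = int(s), int(e)
            if e > length:
                raise ValueError(f"interval ({chrom},{s},{e}) exceeds chromosome length {length}")
            if s < pos:
                raise ValueError(f"overlapping rows on {chrom} at {s}")
            if s > pos:
                rows.append((chrom, pos, s, qui))
            rows.append((chrom, s, e, lab))
            pos = e
        if pos < length:
            rows.append((chrom, pos, length, qui))
    merged: list[list] = []
    for r in rows:
        if merged and merged[-1][0] == r[0] and merged[-1][2] == r[1] and merged[-1][3] == r[3]:
            merged[-1][2] = r[2]
        else:
            merged.append(list(r))
    intervals = pd.DataFrame(merged, columns=["chrom", "start", "end", "state"])
    tissue_id = tissue if tissue is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return Segmentation(tissue_id, intervals, assembly, catalog, bin_size)


def write_segmentation(seg: Segmentation, path: PathLike) -> None:
    """Write the dense 4-column BED; round-trips through read_segmentation."""
    out = _sort_for_write(seg.intervals, seg.assembly)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    """Read a 4-column bedGraph score track (chrom, start, end, score)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "score"], usecols=[0, 1, 2, 3])
    if df.empty:
        raise ValueError(f"{path}: empty score track")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["score"] = df["score"].astype(float)
    return df


def read_gene_table(path: PathLike, fmt: str | None = None) -> GeneTable:
    """Read gene annotations from GFF3/GTF (gene rows) or 6-column BED.

    GFF/GTF 1-based starts are converted to 0-based half-open.  The TSS is
    the interval start on the + strand and the end on the - strand.
    """
    if fmt is None:
        low = str(path).lower()
        fmt = "bed" if low.endswith(".bed") else "gff"
    if fmt == "bed":
        df = read_bed(path)
        if "strand" not in df.columns or "name" not in df.columns:
            raise ValueError("BED gene table needs name and strand columns")
        genes = pd.DataFrame(
            {
                "gene_id": df["name"],
                "chrom": df["chrom"],
                "strand": df["strand"],
                "tss": np.where(df["strand"] == "-", df["end"], df["start"]),
                "tes": np.where(df["strand"] == "-", df["start"], df["end"]),
                "biotype": "protein_coding",
            }
        )
        return GeneTable(genes)
    raw = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "source", "type", "start", "end",
                             "score", "strand", "frame", "attrs"])
    rows = raw[raw["type"].isin(["gene"])]
    if rows.empty:
        rows = raw[raw["type"].isin(["transcript", "mRNA"])]
    if rows.empty:
        raise ValueError(f"{path}: no gene or transcript rows")

    def _attr(attrs: str, keys: tuple[str, ...]) -> str | None:
        for field in attrs.replace("; ", ";").split(";"):
            field = field.strip()
            for key in keys:
                if field.startswith(key):
                    val = field[len(key):].strip(" =\"")
                    return val.strip('"')
        return None

    ids = [
        _attr(a, ("gene_id", "ID=gene:", "ID=")) or f"gene{i}"
        for i, a in enumerate(rows["attrs"])
    ]
    biotypes = [
        _attr(a, ("gene_biotype", "biotype=")) or "protein_coding" for a in rows["attrs"]
    ]
    start0 = rows["start"].astype(np.int64) - 1  # GFF is 1-based inclusive
    end0 = rows["end"].astype(np.int64)
    genes = pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": rows["chrom"].to_numpy(),
            "strand": rows["strand"].to_numpy(),
            "tss": np.where(rows["strand"] == "-", end0, start0),
            "tes": np.where(rows["strand"] == "-", start0, end0),
            "biotype": biotypes,
        }
    )
    return GeneTable(genes.reset_index(drop=True))


def bundled_path(filename: str):
    """Path to a data file shipped with the package."""
    return resources.files("chromdyn.data").joinpath(filename)


def load_susscr11_assembly() -> GenomeAssembly:
    """The susScr11 (Sus scrofa 11.1) chromosome lengths, autosomes + X + Y."""
    with resources.as_file(bundled_path("susScr11.chrom.sizes")) as p:
        return read_chrom_sizes(p, name="susScr11")
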