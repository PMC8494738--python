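"""Interval algebra on (chrom, start, end) tables.

All functions treat intervals as 0-based half-open.  Book-ended intervals
(one ends where the next starts) share no bases and therefore never overlap:
"overlap" always means intersection length >= 1 bp.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "flatten",
    "total_length",
    "intersect",
    "overlap_bases",
    "merge_intervals",
    "clip_intervals",
    "bin_coverage",
]


def _per_chrom(df: pd.DataFrame):
    for chrom, sub in df.groupby("chrom", sort=False):
        yield chrom, sub.sort_values("start")


def flatten(df: pd.DataFrame) -> pd.DataFrame:
    """Base-level union: merge overlapping or book-ended intervals.

    The result covers exactly the same bases with the fewest intervals.
    """
    rows = []
    for chrom, sub in _per_chrom(df):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}
    )


def total_length(df: pd.DataFrame) -> int:
    """Total bp covered (input flattened first, so overlaps count once)."""
    if df.empty:
        return 0
    flat = flatten(df)
    return int((flat["end"] - flat["start"]).sum())


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersection intervals of the base-unions of ``a`` and ``b``."""
    if a.empty or b.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    fa, fb = flatten(a), flatten(b)
    rows = []
    for chrom, sa in _per_chrom(fa):
        sb = fb[fb["chrom"] == chrom]
        if sb.empty:
            continue
        astarts, aends = sa["start"].to_numpy(), sa["end"].to_numpy()
        bstarts, bends = sb["start"].to_numpy(), sb["end"].to_numpy()
        i = j = 0
        while i < len(astarts) and j < len(bstarts):
            s = max(astarts[i], bstarts[j])
            e = min(aends[i], bends[j])
            if e > s:
                rows.append((chrom, s, e))
            if aends[i] <= bends[j]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64} if rows else {}
    )


def overlap_bases(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Bases shared between the unions of two interval sets (symmetric)."""
    inter = intersect(a, b)
    if inter.empty:
        return 0
    return int((inter["end"] - inter["start"]).sum())


def merge_intervals(
    sets: Mapping[str, pd.DataFrame], min_overlap: int = 1
) -> pd.DataFrame:
    """Merge per-tissue interval sets into shared regions with contributors.

    Two intervals belong to the same region when they share at least
    ``min_overlap`` bp, taken as a transitive closure across tissues (the
    1-bp merge rule used to pool one state's regions across tissues).
    Returns a table (chrom, start, end, tissues) where ``tissues`` is the
    sorted tuple of contributing tissue ids; regions are non-overlapping for
    ``min_overlap=1`` and every input interval lands in exactly one region.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    frames = []
    for tissue, df in sets.items():
        if df.empty:
            continue
        f = df[["chrom", "start", "end"]].copy()
        f["tissue"] = tissue
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "tissues"])
    pooled = pd.concat(frames, ignore_index=True)
    rows = []
    for chrom, sub in _per_chrom(pooled):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        tissues = sub["tissue"].to_numpy()
        n = len(starts)
        parent = np.arange(n)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        # sweep: an interval can only reach min_overlap with intervals whose
        # end exceeds its start by at least min_overlap
        active: list[int] = []
        for i in range(n):
            active = [j for j in active if ends[j] - starts[i] >= min_overlap]
            for j in active:
                if min(ends[i], ends[j]) - max(starts[i], starts[j]) >= min_overlap:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
            active.append(i)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            idx = np.array(members)
            rows.append(
                (
                    chrom,
                    int(starts[idx].min()),
                    int(ends[idx].max()),
                    tuple(sorted(set(tissues[idx]))),
                )
            )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "tissues"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def clip_intervals(df: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Pieces of ``df`` falling inside the window [start, end) of ``chrom``."""
    sub = df[df["chrom"] == chrom]
    s = sub["start"].clip(lower=start)
    e = sub["end"].clip(upper=end)
    keep = e > s
    out = pd.DataFrame({"chrom": chrom, "start": s[keep], "end": e[keep]})
    return out.reset_index(drop=True)


def bin_coverage(df: pd.DataFrame, chrom_length: int, chrom: str, bin_size: int) -> np.ndarray:
    """Covered bp of each fixed-size bin of one chromosome.

    Bins tile [0, chrom_length); the final bin may be short.  Input is
    flattened first so overlapping intervals do not double-count.
    """
    n_bins = -(-chrom_length // bin_size)
    cov = np.zeros(n_bins, dtype=np.int64)
    sub = df[df["chrom"] == chrom]
    if sub.empty:
        return cov
    flat = flatten(sub)
    for s, e in zip(flat["start"], flat["end"]):
        s, e = int(s), min(int(e), chrom_length)
        if e <= s:
            continue
        b0, b1 = s // bin_size, (e - 1) // bin_size
        if b0 == b1:
            cov[b0] += e - s
            continue
        cov[b0] += (b0 + 1) * bin_size - s
        cov[b1] += e - b1 * bin_size
        if b1 > b0 + 1:
            cov[b0 + 1 : b1] += bin_size
    return cov
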