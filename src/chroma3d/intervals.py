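"""Interval arithmetic on 0-based half-open genomic coordinates.

All feature tables in this package are pandas DataFrames with at least
``chrom``, ``start``, ``end`` columns, BED-style: 0-based, half-open
``[start, end)``.  These helpers centralise the overlap conventions so
that every module applies the same >= 1 bp rule.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping or abutting intervals per chromosome.

    Returns a minimal sorted set of disjoint intervals covering the same
    bases.  Abutting intervals ([0,5)+[5,9)) are fused, which leaves
    total covered length invariant under splitting.
    """
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def total_length(df: pd.DataFrame) -> int:
    """Total covered bases after merging."""
    merged = merge_intervals(df)
    if merged.empty:
        return 0
    return int((merged["end"] - merged["start"]).sum())


def build_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    """One IntervalTree per chromosome; interval data = row index."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom"):
        t = IntervalTree()
        for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
            if e > s:
                t[int(s):int(e)] = idx
        trees[chrom] = t
    return trees


def overlapping_indices(trees: dict[str, IntervalTree], chrom: str,
                        start: int, end: int) -> list:
    """Row indices of intervals overlapping [start, end) by >= 1 bp."""
    t = trees.get(chrom)
    if t is None or end <= start:
        return []
    return sorted(iv.data for iv in t.overlap(start, end))


def overlaps_any(trees: dict[str, IntervalTree], chrom: str,
                 start: int, end: int) -> bool:
    t = trees.get(chrom)
    if t is None or end <= start:
        return False
    return t.overlaps(start, end)


def flag_overlaps(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: overlaps >= 1 bp of any subject interval."""
    trees = build_trees(subject)
    return np.fromiter(
        (overlaps_any(trees, c, s, e)
         for c, s, e in zip(query["chrom"], query["start"], query["end"])),
        dtype=bool, count=len(query))


def promoter_windows(genes: pd.DataFrame, upstream: int = 3000,
                     chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Strand-aware upstream promoter windows, clipped to the chromosome.

    For a + strand gene the window is [TSS-upstream, TSS); for a - strand
    gene the TSS is the interval end and the window is [end, end+upstream).
    """
    rows = []
    for row in genes.itertuples(index=False):
        strand = getattr(row, "strand", "+")
        if strand == "-":
            s, e = row.end, row.end + upstream
        else:
            s, e = row.start - upstream, row.start
        s = max(0, s)
        if chrom_sizes is not None:
            e = min(e, chrom_sizes.get(row.chrom, e))
        rows.append((row.chrom, s, e, getattr(row, "gene_id", ".")))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
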