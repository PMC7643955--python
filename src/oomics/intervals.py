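"""Genomic interval primitives.

Coordinates are 0-based half-open everywhere inside the package; GTF-style
1-based inclusive coordinates are converted at the I/O boundary. Abutting
half-open intervals ([a, b) and [b, c)) do NOT merge: merging requires at
least one shared base.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

Interval = Tuple[int, int]
Region = Tuple[str, int, int]  # (chrom, start, end), 0-based half-open


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge strictly overlapping intervals on a single chromosome.

    Returns the minimal set of maximal intervals covering the same bases.
    Half-open abutting intervals are kept separate.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if e < s:
            raise ValueError(f"malformed interval [{s}, {e})")
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge a (chrom, start, end) frame per chromosome."""
    out = []
    for chrom, sub in regions.groupby("chrom", sort=True):
        for s, e in merge_intervals(zip(sub["start"], sub["end"])):
            out.append((chrom, s, e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


class GenomeIntervals:
    """Overlap index over a (chrom, start, end[, ...]) frame.

    Thin per-chromosome interval-tree wrapper used for promoter / exon /
    UTR / repeat / accessibility lookups. Empty intervals are ignored
    (half-open convention: [s, s) covers no base).
    """

    def __init__(self, frame: pd.DataFrame):
        self._trees: dict[str, IntervalTree] = {}
        self._frame = frame.reset_index(drop=True)
        for idx, row in self._frame.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if e > s:
                self._trees.setdefault(str(row["chrom"]), IntervalTree()).addi(s, e, idx)

    def __len__(self) -> int:
        return len(self._frame)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(str(chrom))
        return bool(tree is not None and end > start and tree.overlaps(start, end))

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Rows of the indexed frame overlapping the query by >= 1 bp."""
        tree = self._trees.get(str(chrom))
        if tree is None or end <= start:
            return self._frame.iloc[0:0]
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return self._frame.iloc[hits]


def regions_overlapping_track(regions: pd.DataFrame, track: pd.DataFrame) -> pd.Series:
    """Boolean per region: does it overlap any track interval by >= 1 bp?"""
    index = GenomeIntervals(track)
    return pd.Series(
        [index.overlaps(c, s, e) for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])],
        index=regions.index,
    )
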