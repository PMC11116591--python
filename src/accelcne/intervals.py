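"""Half-open genomic intervals and the interval algebra shared by all stages.

Every public coordinate in the package is 0-based half-open (BED
convention); GFF3's 1-based inclusive coordinates are converted at the
I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import groupby


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int
    id: str | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_id(self, new_id: str) -> "GenomicInterval":
        return replace(self, id=new_id)


def _by_chrom(intervals):
    key = lambda iv: iv.chrom
    return groupby(sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)), key)


def merge_intervals(intervals) -> list:
    """Union of intervals as maximal disjoint intervals, sorted by (chrom, start)."""
    out = []
    for chrom, group in _by_chrom(intervals):
        cur_start = cur_end = None
        for iv in group:
            if cur_end is None or iv.start > cur_end:
                if cur_end is not None:
                    out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
            else:
                cur_end = max(cur_end, iv.end)
        if cur_end is not None:
            out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def subtract_intervals(a, b) -> list:
    """Maximal sub-intervals of ``a`` that overlap no base of ``b``."""
    b_merged = {}
    for chrom, group in _by_chrom(b):
        b_merged[chrom] = list(group)
    b_by_chrom = {
        chrom: merge_intervals(group) for chrom, group in b_merged.items()
    }
    out = []
    for iv in sorted(a, key=lambda x: (x.chrom, x.start, x.end)):
        cursor = iv.start
        for blocker in b_by_chrom.get(iv.chrom, ()):
            if blocker.end <= cursor:
                continue
            if blocker.start >= iv.end:
                break
            if blocker.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, blocker.start, id=iv.id))
            cursor = max(cursor, blocker.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end, id=iv.id))
    return out


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """0 for overlapping intervals, else the gap in bp; inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end)


def point_distance(iv: GenomicInterval, chrom: str, pos: int) -> float:
    """Distance from a single position (e.g. a TSS) to an interval."""
    return interval_distance(iv, GenomicInterval(chrom, pos, pos + 1))


def total_bp(intervals) -> int:
    """Total bases covered (input need not be disjoint)."""
    return sum(iv.length for iv in merge_intervals(intervals))
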