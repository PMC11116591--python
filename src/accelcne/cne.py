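"""Conserved non-coding elements: conserved regions minus coding sequence.

Coding bases (the merged union of annotated CDS features) are subtracted
from each conserved element and the remaining fragments are kept if they
are at least ``min_len`` (default 20) bp long — the threshold is
inclusive. Fragments keep a pointer to their parent conserved element.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, merge_intervals, subtract_intervals

MIN_CNE_LENGTH = 20


@dataclass
class CNE:
    interval: GenomicInterval
    id: str
    source_id: str | None  # parent conserved element

    @property
    def length(self) -> int:
        return self.interval.length


def extract_cnes(conserved, cds, min_len: int = MIN_CNE_LENGTH) -> list:
    """Subtract merged CDS from conserved intervals, then length-filter.

    ``conserved`` may be ConservedElement objects or bare intervals.
    Ids are assigned deterministically in (chrom, start) order.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ivs = [getattr(c, "interval", c) for c in conserved]
    # coalesce overlapping/abutting conserved intervals so the length
    # filter sees maximal conserved runs; keep parent ids (joined when
    # runs coalesce — Viterbi output is disjoint, so normally one id)
    ivs = sorted(ivs, key=lambda v: (v.chrom, v.start, v.end))
    coalesced: list = []
    for v in ivs:
        if (coalesced and coalesced[-1].chrom == v.chrom
                and v.start <= coalesced[-1].end):
            prev = coalesced[-1]
            ids = {i for i in (prev.id, v.id) if i is not None}
            coalesced[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, v.end),
                id="+".join(sorted(ids)) or None,
            )
        else:
            coalesced.append(v)
    cds_merged = merge_intervals(cds)
    fragments = subtract_intervals(coalesced, cds_merged)
    kept = sorted(
        (f for f in fragments if f.length >= min_len),
        key=lambda f: (f.chrom, f.start),
    )
    return [
        CNE(
            GenomicInterval(f.chrom, f.start, f.end, id=f"cne_{i:06d}"),
            id=f"cne_{i:06d}",
            source_id=f.id,
        )
        for i, f in enumerate(kept)
    ]
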