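"""Recurrent hibernation DEGs and their overlap with acceleration targets.

Gene lists from independent expression studies are merged by gene
symbol (uppercased); a gene is a recurrent DEG if at least ``m``
distinct studies (default 2) report it, regardless of tissue or
species. The overlap table intersects recurrent DEGs with genes near
elements accelerated in >= k_min lineages for each k_min.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

RECURRENCE = 2


@dataclass
class DEGStudy:
    study_id: str
    genes: tuple

    def __post_init__(self):
        if not self.study_id:
            raise ValueError("study id must be non-empty")
        seen, dedup = set(), []
        for g in self.genes:
            g = str(g).upper()
            if g not in seen:
                seen.add(g)
                dedup.append(g)
        self.genes = tuple(dedup)

    @classmethod
    def from_tsv(cls, study_id: str, handle) -> "DEGStudy":
        df = pd.read_csv(handle, sep="\t")
        col = "gene" if "gene" in df.columns else df.columns[0]
        return cls(study_id, tuple(df[col].astype(str)))


def recurrent_degs(studies, m: int = RECURRENCE) -> set:
    """Genes reported by at least ``m`` distinct studies."""
    studies = list(studies)
    if len(studies) < m:
        raise ValueError(f"need at least {m} studies, got {len(studies)}")
    counts: Counter = Counter()
    for st in studies:
        counts.update(set(st.genes))
    return {g for g, n in counts.items() if n >= m}


def overlap_table(degs: set, share, cne_to_genes: dict,
                  k_mins=(2, 3, 4, 5)) -> pd.DataFrame:
    """Recurrent DEGs near elements accelerated in >= k_min lineages.

    Returns one row per k_min with the overlap count and the sorted
    gene list; counts are nonincreasing in k_min by construction.
    """
    degs = {str(g).upper() for g in degs}
    rows = []
    for k_min in k_mins:
        genes = set()
        for cid in share.cnes_with_at_least(k_min):
            genes |= {g.upper() for g in cne_to_genes.get(cid, set())}
        hit = sorted(degs & genes)
        rows.append({"k_min": k_min, "n_overlap": len(hit),
                     "genes": ",".join(hit)})
    return pd.DataFrame(rows)
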