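"""Lineage sharing of accelerated elements.

For each element, the lineage count k is the number of tested branches
on which it is significantly accelerated. Because "shared by at least
two lineages" and "shared by exactly two" read differently, both the
exact-k histogram and the cumulative >=k counts are emitted, explicitly
labelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class LineageShareTable:
    per_cne: pd.DataFrame  # cne_id, lineage_count, branches (comma-joined)
    summary: pd.DataFrame  # k, n_exact, n_at_least
    branches: tuple

    def cnes_with_at_least(self, k: int) -> list:
        df = self.per_cne
        return df.loc[df["lineage_count"] >= k, "cne_id"].tolist()


def lineage_share(results: pd.DataFrame, branches=None) -> LineageShareTable:
    """Build the lineage-share table from a full (CNE x branch) result table.

    Every (cne, branch) pair must be present exactly once; a missing
    pair is an error naming it.
    """
    if branches is None:
        branches = tuple(sorted(results["branch"].unique()))
    branches = tuple(branches)
    pivot = results.pivot_table(
        index="cne_id", columns="branch", values="significant",
        aggfunc="first",
    )
    for b in branches:
        if b not in pivot.columns:
            raise ValueError(f"missing (CNE, branch) results for branch {b!r}")
    pivot = pivot[list(branches)]
    if pivot.isna().any().any():
        cne, br = next(
            (i, c) for i in pivot.index for c in pivot.columns
            if pd.isna(pivot.at[i, c])
        )
        raise ValueError(f"missing result for pair ({cne!r}, {br!r})")
    counts = pivot.astype(bool).sum(axis=1)
    sig_sets = pivot.astype(bool).apply(
        lambda row: ",".join(b for b in branches if row[b]), axis=1
    )
    per_cne = pd.DataFrame(
        {
            "cne_id": pivot.index,
            "lineage_count": counts.to_numpy(),
            "branches": sig_sets.to_numpy(),
        }
    ).sort_values("cne_id", ignore_index=True)

    n_branches = len(branches)
    ks = list(range(n_branches + 1))
    n_exact = [int((per_cne["lineage_count"] == k).sum()) for k in ks]
    n_at_least = [int((per_cne["lineage_count"] >= k).sum()) for k in ks]
    summary = pd.DataFrame({"k": ks, "n_exact": n_exact, "n_at_least": n_at_least})
    return LineageShareTable(per_cne=per_cne, summary=summary, branches=branches)
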