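"""Gene assignment to elements and GO-term enrichment with graph decorrelation.

Genes are linked to elements GREAT-style: a gene is assigned to every
element whose distance to the gene's TSS is at most ``d_max`` (1 Mb by
default, inclusive) on the same chromosome. Enrichment of GO biological
process terms among genes near accelerated elements is tested against
genes near all elements with a one-sided Fisher's exact
(hypergeometric upper tail), either per term ("classic") or with the
"elim" decorrelation that removes the genes of significantly enriched
children before testing their ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .acceleration import bh_fdr

D_MAX = 1_000_000
MIN_NODE_SIZE = 5
ELIM_THRESHOLD = 0.01


def assign_genes(cnes, genes, d_max: int = D_MAX) -> tuple:
    """GREAT-style assignment maps (cne_id -> gene set, gene -> cne_id set).

    A gene qualifies for an element iff its TSS is on the same
    chromosome and the TSS-to-element gap is <= d_max ("within 1 Mb" is
    inclusive); a TSS inside the element has distance 0. Genes may be
    assigned to many elements and vice versa.
    """
    cne_to_genes: dict = {getattr(c, "id", c.interval.id): set() for c in cnes}
    gene_to_cnes: dict = {g.gene_id: set() for g in genes}
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for c in cnes:
        iv = c.interval
        cid = getattr(c, "id", iv.id)
        for g in by_chrom.get(iv.chrom, ()):
            if g.tss < iv.end and g.tss >= iv.start:
                dist = 0
            elif g.tss >= iv.end:
                dist = g.tss - iv.end
            else:
                dist = iv.start - g.tss - 1
            if dist <= d_max:
                cne_to_genes[cid].add(g.gene_id)
                gene_to_cnes[g.gene_id].add(cid)
    return cne_to_genes, gene_to_cnes


def target_background_sets(share, cne_to_genes: dict, k_min: int | None = None,
                           branch: str | None = None,
                           results: pd.DataFrame | None = None) -> tuple:
    """(target, background) gene sets for enrichment.

    Target = genes near elements accelerated in >= k_min lineages, or —
    with ``branch`` and the full result table — near elements
    significant on that branch. Background = genes near all elements.
    """
    background = set().union(*cne_to_genes.values()) if cne_to_genes else set()
    if branch is not None:
        if results is None:
            raise ValueError("branch targets require the result table")
        sig = results[(results["branch"] == branch) & results["significant"]]
        target_cnes = sig["cne_id"].tolist()
    else:
        if k_min is None:
            raise ValueError("either k_min or branch must be given")
        n_br = len(share.branches)
        if not 1 <= k_min <= n_br:
            raise ValueError(f"k_min must be in 1..{n_br}, got {k_min}")
        target_cnes = share.cnes_with_at_least(k_min)
    target = set()
    for cid in target_cnes:
        target |= cne_to_genes.get(cid, set())
    return target, background


@dataclass
class GODag:
    """A rooted is_a DAG over GO terms plus direct gene annotations."""

    graph: nx.DiGraph  # edge child -> parent
    annotations: dict  # gene -> set of directly annotated terms
    _term_genes: dict | None = field(default=None, init=False, repr=False)

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO graph contains a cycle")
        orphans = sorted(
            {t for terms in self.annotations.values() for t in terms}
            - set(self.graph.nodes)
        )
        if orphans:
            raise ValueError(f"annotations to terms absent from the DAG: {orphans}")

    @classmethod
    def from_tables(cls, edges: pd.DataFrame, annotations: pd.DataFrame) -> "GODag":
        """Build from edge list (child, parent) and annotation (gene, term) tables."""
        g = nx.DiGraph()
        g.add_nodes_from(edges["child"])
        g.add_nodes_from(edges["parent"])
        g.add_edges_from(edges[["child", "parent"]].itertuples(index=False))
        ann: dict = {}
        for gene, term in annotations[["gene", "term"]].itertuples(index=False):
            ann.setdefault(str(gene), set()).add(str(term))
        return cls(g, ann)

    def ancestors(self, term: str) -> set:
        return nx.descendants(self.graph, term)  # edges point child -> parent

    def term_genes(self) -> dict:
        """True-path closure: term -> genes annotated to it or any descendant."""
        if self._term_genes is None:
            closure: dict = {t: set() for t in self.graph.nodes}
            for gene, terms in self.annotations.items():
                for t in terms:
                    closure[t].add(gene)
                    for anc in self.ancestors(t):
                        closure[anc].add(gene)
            self._term_genes = closure
        return self._term_genes

    def depths(self) -> dict:
        """Longest path to a root (ancestor-less term), for elim ordering."""
        order = list(nx.topological_sort(self.graph))  # children before parents
        depth: dict = {}
        for t in reversed(order):  # parents first
            parents = list(self.graph.successors(t))
            depth[t] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth


def go_enrichment(
    target: set,
    background: set,
    dag: GODag,
    method: str = "elim",
    alpha: float = 0.05,
    min_node_size: int = MIN_NODE_SIZE,
    elim_threshold: float = ELIM_THRESHOLD,
) -> pd.DataFrame:
    """Per-term one-sided enrichment of ``target`` within ``background``.

    p is the hypergeometric upper tail Pr(X >= k) with N = |background|,
    K = background genes annotated to the term, n = |target|. Terms with
    K < min_node_size are skipped. ``elim`` processes terms deepest
    first (ties by term id) and removes the genes of children reaching
    p <= elim_threshold from all their ancestors before those are
    tested, so a parent is only credited signal its children do not
    explain. BH FDR is applied across the tested terms.
    """
    if not target <= background:
        raise ValueError("target genes must be a subset of the background")
    if method not in ("classic", "elim"):
        raise ValueError(f"unknown method {method!r}")
    term_genes = dag.term_genes()
    N, n = len(background), len(target)
    depth = dag.depths()
    order = sorted(term_genes, key=lambda t: (-depth[t], t))
    removed: dict = {t: set() for t in term_genes}
    rows = []
    for term in order:
        genes = (term_genes[term] & background) - removed[term]
        K = len(genes)
        if K < min_node_size:
            continue
        k = len(genes & target)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(max(p, 5e-324), 1.0)
        rows.append(
            {
                "term": term,
                "bg_count": K,
                "target_count": k,
                "expected": n * K / N if N else 0.0,
                "p": p,
            }
        )
        if method == "elim" and p <= elim_threshold:
            for anc in dag.ancestors(term):
                removed[anc] |= genes
    df = pd.DataFrame(rows, columns=["term", "bg_count", "target_count",
                                     "expected", "p"])
    if not df.empty:
        q, flags = bh_fdr(df["p"].to_numpy(), alpha)
        df["q"], df["significant"] = q, flags
    else:
        df["q"], df["significant"] = [], []
    return df.sort_values(["p", "term"], ignore_index=True)
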