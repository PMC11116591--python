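import itertools
import math

import numpy as np
import pandas as pd
import pytest

from accelcne.cne import CNE
from accelcne.enrichment import (
    GODag,
    assign_genes,
    go_enrichment,
    target_background_sets,
)
from accelcne.genome_io import GeneRecord
from accelcne.intervals import GenomicInterval


def cne(start, end, cid, chrom="chr1"):
    return CNE(GenomicInterval(chrom, start, end, id=cid), cid, None)


def gene(gid, tss, chrom="chr1", strand="+"):
    return GeneRecord(gid, chrom, tss, strand,
                      GenomicInterval(chrom, max(tss - 100, 0), tss + 101))


class TestAssignGenes:
    def test_nearby_gene_assigned(self):
        c2g, g2c = assign_genes([cne(1000, 1100, "c1")],
                                [gene("G1", 501_000)])
        assert c2g["c1"] == {"G1"}
        assert g2c["G1"] == {"c1"}

    def test_exactly_one_megabase_inclusive(self):
        c = cne(1000, 1100, "c1")
        inside = gene("G1", 1100 + 1_000_000)      # gap exactly 1 Mb
        outside = gene("G2", 1100 + 1_000_001)     # one bp beyond
        c2g, _ = assign_genes([c], [inside, outside])
        assert c2g["c1"] == {"G1"}

    def test_tss_inside_element_distance_zero(self):
        c2g, _ = assign_genes([cne(1000, 1100, "c1")], [gene("G1", 1050)])
        assert c2g["c1"] == {"G1"}

    def test_other_chromosome_never_assigned(self):
        c2g, _ = assign_genes([cne(1000, 1100, "c1")],
                              [gene("G1", 1000, chrom="chr2")])
        assert c2g["c1"] == set()

    def test_multi_assignment_allowed(self):
        cnes = [cne(0, 50, "c1"), cne(5000, 5100, "c2")]
        c2g, g2c = assign_genes(cnes, [gene("G1", 2000)])
        assert g2c["G1"] == {"c1", "c2"}


class FakeShare:
    def __init__(self, mapping, branches=("a", "b", "c", "d", "e")):
        self.mapping = mapping
        self.branches = branches

    def cnes_with_at_least(self, k):
        return [cid for cid, kk in self.mapping.items() if kk >= k]


class TestTargetBackground:
    C2G = {"c1": {"G1", "G2"}, "c2": {"G2", "G3"}, "c3": {"G4"}}

    def test_hand_derived_sets(self):
        share = FakeShare({"c1": 3, "c2": 1, "c3": 0})
        target, background = target_background_sets(share, self.C2G, k_min=2)
        assert target == {"G1", "G2"}
        assert background == {"G1", "G2", "G3", "G4"}

    def test_all_accelerated_target_equals_background(self):
        share = FakeShare({"c1": 5, "c2": 5, "c3": 5})
        target, background = target_background_sets(share, self.C2G, k_min=2)
        assert target == background

    def test_none_accelerated_empty_target(self):
        share = FakeShare({"c1": 0, "c2": 0, "c3": 0})
        target, _ = target_background_sets(share, self.C2G, k_min=2)
        assert target == set()

    def test_k_min_out_of_range(self):
        share = FakeShare({"c1": 0})
        with pytest.raises(ValueError):
            target_background_sets(share, self.C2G, k_min=6)


def simple_dag(edges, annotations):
    return GODag.from_tables(
        pd.DataFrame(edges, columns=["child", "parent"]),
        pd.DataFrame(annotations, columns=["gene", "term"]),
    )


def hypergeom_tail_enumeration(N, K, n, k):
    """Exhaustive: fraction of n-subsets of N with >= k of the K marked."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return hits / total


class TestGoEnrichment:
    def test_hypergeometric_example(self):
        # 10/100 background genes annotated; 4/10 target genes
        genes = [f"g{i}" for i in range(100)]
        ann = [(g, "T") for g in genes[:10]]
        dag = simple_dag([("T", "root")], ann)
        target = set(genes[:4]) | set(genes[50:56])  # 4 annotated of 10
        df = go_enrichment(target, set(genes), dag, method="classic")
        row = df[df["term"] == "T"].iloc[0]
        from scipy.stats import hypergeom

        assert row["p"] == pytest.approx(float(hypergeom.sf(3, 100, 10, 10)))
        assert row["p"] == pytest.approx(
            hypergeom_tail_enumeration(100, 10, 10, 4), rel=1e-9
        )

    def test_target_equals_background_all_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        dag = simple_dag([("T", "root")], [(g, "T") for g in genes[:8]])
        df = go_enrichment(set(genes), set(genes), dag, method="classic")
        assert (df["p"] == 1.0).all()

    def test_elim_parent_at_least_classic_p(self):
        # parent's signal comes entirely from a significant child
        child_genes = [f"g{i}" for i in range(8)]
        other = [f"h{i}" for i in range(42)]
        ann = [(g, "child") for g in child_genes]
        ann += [(g, "parent") for g in other[:2]]
        dag = simple_dag([("child", "parent"), ("parent", "root")], ann)
        background = set(child_genes) | set(other)
        target = set(child_genes)  # perfectly enriched in the child term
        classic = go_enrichment(target, background, dag, method="classic",
                                min_node_size=2)
        elim = go_enrichment(target, background, dag, method="elim",
                             min_node_size=2)
        p_classic = classic.set_index("term")["p"]
        p_elim = elim.set_index("term")["p"]
        assert p_elim["child"] == pytest.approx(p_classic["child"])
        assert p_elim["parent"] >= p_classic["parent"]
        assert p_elim["parent"] > 0.5  # child's genes were removed

    def test_true_path_propagation_matches_bruteforce(self, rng):
        for _ in range(10):
            n_terms = int(rng.integers(5, 20))
            terms = [f"t{i}" for i in range(n_terms)]
            edges = []
            for i in range(1, n_terms):
                for p in rng.choice(i, size=min(int(rng.integers(1, 3)), i),
                                    replace=False):
                    edges.append((terms[i], terms[int(p)]))
            genes = [f"g{i}" for i in range(15)]
            ann = [
                (g, terms[int(t)])
                for g in genes
                for t in rng.choice(n_terms, size=2)
            ]
            dag = simple_dag(edges, ann)
            closure = dag.term_genes()
            # oracle: follow every gene's annotation up through edge list
            parents = {}
            for c, p in edges:
                parents.setdefault(c, set()).add(p)
            for g, t in ann:
                up = {t}
                frontier = [t]
                while frontier:
                    cur = frontier.pop()
                    for p in parents.get(cur, ()):
                        if p not in up:
                            up.add(p)
                            frontier.append(p)
                for term in up:
                    assert g in closure[term]

    def test_min_node_size_skips_small_terms(self):
        genes = [f"g{i}" for i in range(30)]
        dag = simple_dag([("small", "root"), ("big", "root")],
                         [(genes[0], "small")] +
                         [(g, "big") for g in genes[:10]])
        df = go_enrichment(set(genes[:5]), set(genes), dag, method="classic",
                           min_node_size=5)
        assert "small" not in set(df["term"])
        assert "big" in set(df["term"])

    def test_orphan_annotation_rejected(self):
        with pytest.raises(ValueError, match="orphan|absent"):
            GODag.from_tables(
                pd.DataFrame([("a", "root")], columns=["child", "parent"]),
                pd.DataFrame([("g1", "nowhere")], columns=["gene", "term"]),
            )

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            simple_dag([("a", "b"), ("b", "a")], [])

    def test_target_not_subset_rejected(self):
        dag = simple_dag([("T", "root")], [("g1", "T")])
        with pytest.raises(ValueError):
            go_enrichment({"gX"}, {"g1"}, dag)
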