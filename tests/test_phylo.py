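import numpy as np
import pytest

from accelcne import phylo
from accelcne.phylo import (
    BranchScaling,
    NewickError,
    PhyloModel,
    SubstModel,
    alignment_log_likelihoods,
    column_log_likelihood,
    fit_scales,
    read_newick,
)
from accelcne.simulate import sample_columns

from conftest import brute_force_column_loglik, random_model, random_tree_newick


class TestNewick:
    def test_two_leaf_lengths(self):
        tree = read_newick("(A:0.1,B:0.2);")
        assert sorted(tree.leaf_names) == ["A", "B"]
        assert tree.lengths[tree.branch_node("A")] == pytest.approx(0.1)
        assert tree.lengths[tree.branch_node("B")] == pytest.approx(0.2)

    def test_round_trip_preserves_topology_and_lengths(self):
        text = "((A:0.1,B:0.2)ab:0.05,(C:0.3,D:0.4):0.07);"
        tree = read_newick(text)
        again = read_newick(tree.to_newick())
        assert again.to_newick() == tree.to_newick()
        assert again.names[again.branch_node("ab")] == "ab"
        np.testing.assert_allclose(sorted(again.lengths), sorted(tree.lengths))

    def test_unbalanced_parenthesis_raises(self):
        with pytest.raises(NewickError):
            read_newick("(A:0.1,B:0.2")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            read_newick("(A:0.1,B:-0.2);")

    def test_internal_labels_addressable(self):
        tree = read_newick("((X:0.1,Y:0.1)anc:0.2,Z:0.3);")
        assert tree.lengths[tree.branch_node("anc")] == pytest.approx(0.2)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, hky):
        np.testing.assert_allclose(hky.transition_matrix(0.0), np.eye(4),
                                   atol=1e-12)

    def test_long_time_reaches_equilibrium(self, jc):
        P = jc.transition_matrix(100.0)
        np.testing.assert_allclose(P, np.full((4, 4), 0.25), atol=1e-10)

    def test_jc69_closed_form(self, jc):
        # diagonal 1/4 + 3/4 e^{-4t/3}; off-diagonal 1/4 - 1/4 e^{-4t/3}
        t = 0.1
        P = jc.transition_matrix(t)
        diag = 0.25 + 0.75 * np.exp(-4 * t / 3)
        off = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = np.full((4, 4), off)
        np.fill_diagonal(expected, diag)
        np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_rows_stochastic(self, rng):
        model = random_model(rng)
        for t in (0.0, 0.01, 0.3, 2.0):
            P = model.transition_matrix(t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert P.min() >= 0 and P.max() <= 1

    def test_chapman_kolmogorov(self, rng):
        for _ in range(5):
            model = random_model(rng)
            t1, t2 = rng.uniform(0.01, 1.0, size=2)
            lhs = model.transition_matrix(t1) @ model.transition_matrix(t2)
            np.testing.assert_allclose(lhs, model.transition_matrix(t1 + t2),
                                       atol=1e-10)

    def test_negative_time_rejected(self, jc):
        with pytest.raises(ValueError):
            jc.transition_matrix(-0.1)


class TestColumnLikelihood:
    def test_single_leaf_is_root_prior(self, jc):
        pm = PhyloModel(read_newick("(A:0.1);"), jc)
        assert column_log_likelihood(pm, {"A": "A"}) == pytest.approx(
            np.log(0.25), abs=1e-12
        )

    def test_two_leaf_jc_closed_form(self, jc):
        pm = PhyloModel(read_newick("(A:0.1,B:0.2);"), jc)
        P1, P2 = jc.transition_matrix(0.1), jc.transition_matrix(0.2)
        expected = np.log(sum(0.25 * P1[x, 0] * P2[x, 0] for x in range(4)))
        assert column_log_likelihood(pm, {"A": "A", "B": "A"}) == pytest.approx(
            expected, abs=1e-12
        )

    def test_gap_and_n_are_missing(self, jc):
        pm = PhyloModel(read_newick("(A:0.1,B:0.2);"), jc)
        base = column_log_likelihood(pm, {"A": "C"})
        assert column_log_likelihood(pm, {"A": "C", "B": "-"}) == pytest.approx(base)
        assert column_log_likelihood(pm, {"A": "C", "B": "N"}) == pytest.approx(base)

    def test_unknown_species_rejected(self, jc):
        pm = PhyloModel(read_newick("(A:0.1,B:0.2);"), jc)
        with pytest.raises(KeyError):
            column_log_likelihood(pm, {"A": "C", "Z": "G"})

    def test_matches_brute_force_with_scaling(self, rng):
        for _ in range(20):
            n_leaves = int(rng.integers(2, 6))
            pm = PhyloModel(read_newick(random_tree_newick(rng, n_leaves)),
                            random_model(rng))
            target = pm.tree.leaf_names[0]
            scaling = BranchScaling(
                s=float(rng.uniform(0.2, 3.0)),
                branch_scales={target: float(rng.uniform(1.0, 8.0))},
            )
            column = {
                nm: "ACGTN-"[int(rng.integers(0, 6))]
                for nm in pm.tree.leaf_names
            }
            if all(c in "N-" for c in column.values()):
                column[target] = "A"
            got = column_log_likelihood(pm, column, scaling)
            want = brute_force_column_loglik(pm, column, scaling)
            assert got == pytest.approx(want, abs=1e-9)

    def test_reroot_invariance_reversible(self, hky):
        # same unrooted 4-leaf tree, root placed at both ends of the
        # internal branch (pulley principle for reversible models)
        t1 = PhyloModel(
            read_newick("((A:0.1,B:0.2):0.12,(C:0.3,D:0.15):0.0);"), hky
        )
        t2 = PhyloModel(
            read_newick("((A:0.1,B:0.2):0.0,(C:0.3,D:0.15):0.12);"), hky
        )
        for col in ({"A": "A", "B": "C", "C": "G", "D": "T"},
                    {"A": "A", "B": "A", "C": "A", "D": "C"}):
            assert column_log_likelihood(t1, col) == pytest.approx(
                column_log_likelihood(t2, col), abs=1e-10
            )

    def test_columns_independent(self, pm16, rng):
        species, cols = sample_columns(pm16, 25, rng)
        per_col = alignment_log_likelihoods(pm16, species, cols)
        singles = [
            column_log_likelihood(
                pm16, {sp: "ACGT"[cols[i, j]] for i, sp in enumerate(species)}
            )
            for j in range(cols.shape[1])
        ]
        np.testing.assert_allclose(per_col, singles, atol=1e-9)


class TestFitScales:
    def test_recovers_doubled_rate(self, pm16, rng):
        species, cols = sample_columns(pm16, 500, rng, BranchScaling(s=2.0))
        fit = fit_scales(pm16, species, cols)
        assert 1.6 <= fit.scaling.s <= 2.4
        assert fit.converged

    def test_neutral_data_gives_unit_scale(self, pm16, rng):
        species, cols = sample_columns(pm16, 800, rng)
        fit = fit_scales(pm16, species, cols)
        assert 0.85 <= fit.scaling.s <= 1.15

    def test_invariant_columns_drive_scale_to_lower_bound(self, pm16):
        species = pm16.tree.leaf_names
        cols = np.zeros((len(species), 30), dtype=np.int8)  # all A
        fit = fit_scales(pm16, species, cols)
        assert fit.scaling.s <= 1.5e-4

    def test_monotone_improvement_over_start(self, pm16, rng):
        species, cols = sample_columns(pm16, 60, rng, BranchScaling(s=0.31))
        start = alignment_log_likelihoods(pm16, species, cols).sum()
        fit = fit_scales(pm16, species, cols, branch="batAnc")
        assert fit.log_likelihood >= start - 1e-9

    def test_all_missing_rejected(self, pm16):
        species = pm16.tree.leaf_names
        cols = np.full((len(species), 5), phylo.MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            fit_scales(pm16, species, cols)
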