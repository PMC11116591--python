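import numpy as np
import pytest

from accelcne.conservation import (
    BlockDecoding,
    ConservationParams,
    call_elements,
    decode,
    decode_block,
    hmm_params,
)
from accelcne.genome_io import AlignmentBlock, MafRow
from accelcne.phylo import BranchScaling
from accelcne.simulate import sample_columns


def block_from_columns(species, cols, chrom="chr1", start=0):
    rows = []
    for i, sp in enumerate(species):
        text = "".join("ACGT"[b] for b in cols[i])
        rows.append(MafRow(sp, chrom, start, cols.shape[1], "+", 10**6, text))
    return AlignmentBlock(rows)


class TestHmmParams:
    def test_published_parameterization(self):
        mu, nu = hmm_params(45, 0.3)
        assert mu == pytest.approx(1 / 45)
        assert nu == pytest.approx((1 / 45) * 0.3 / 0.7)
        assert nu == pytest.approx(0.009524, abs=5e-7)

    def test_symmetric_coverage(self):
        mu, nu = hmm_params(30, 0.5)
        assert nu == pytest.approx(mu)

    def test_stationary_fraction_identity(self, rng):
        for _ in range(20):
            L = float(rng.uniform(2, 200))
            c = float(rng.uniform(0.05, 0.95))
            mu, nu = hmm_params(L, c)
            assert nu / (mu + nu) == pytest.approx(c, abs=1e-12)

    def test_degenerate_coverage_rejected(self):
        with pytest.raises(ValueError):
            hmm_params(45, 1.0)
        with pytest.raises(ValueError):
            hmm_params(45, 0.0)
        with pytest.raises(ValueError):
            ConservationParams(rho=0.31, expected_length=45, target_coverage=1.5)


class TestDecode:
    def test_forward_backward_agree(self, pm16, rng):
        species, cols = sample_columns(pm16, 300, rng)
        dec = decode_block(block_from_columns(species, cols), pm16,
                          ConservationParams())
        assert dec.log_forward == pytest.approx(dec.log_backward, abs=1e-8)
        assert dec.log_viterbi <= dec.log_forward + 1e-9

    def test_posterior_is_proper_probability(self, pm16, rng):
        species, cols = sample_columns(pm16, 200, rng)
        dec = decode_block(block_from_columns(species, cols), pm16,
                          ConservationParams())
        assert np.all(dec.posterior >= 0) and np.all(dec.posterior <= 1)

    def test_neutral_simulation_rarely_called(self, pm16, rng):
        species, cols = sample_columns(pm16, 4000, rng)
        dec = decode_block(block_from_columns(species, cols), pm16,
                          ConservationParams())
        assert dec.posterior.mean() < 0.3
        assert dec.viterbi.mean() < 0.05

    def test_implanted_element_recovered(self, pm16, rng):
        params = ConservationParams()
        species, left = sample_columns(pm16, 300, rng)
        _, elem = sample_columns(pm16, 60, rng, BranchScaling(s=params.rho))
        _, right = sample_columns(pm16, 300, rng)
        cols = np.concatenate([left, elem, right], axis=1)
        dec = decode_block(block_from_columns(species, cols), pm16, params)
        overlap = dec.viterbi[300:360].mean()
        assert overlap >= 0.8

    def test_rho_near_one_posterior_equals_prior(self, pm16, rng):
        params = ConservationParams(rho=1 - 1e-9)
        species, cols = sample_columns(pm16, 100, rng)
        dec = decode_block(block_from_columns(species, cols), pm16, params)
        np.testing.assert_allclose(dec.posterior, params.target_coverage,
                                   atol=1e-6)

    def test_empty_alignment_rejected(self, pm16):
        with pytest.raises(ValueError):
            decode([], pm16, ConservationParams())

    def test_split_decode_differs_only_near_split(self, pm16, rng):
        params = ConservationParams()
        species, cols = sample_columns(pm16, 400, rng)
        whole = decode_block(block_from_columns(species, cols), pm16, params)
        left = decode_block(block_from_columns(species, cols[:, :200]), pm16,
                            params)
        right = decode_block(
            block_from_columns(species, cols[:, 200:], start=200), pm16, params
        )
        split_post = np.concatenate([left.posterior, right.posterior])
        away = np.r_[0:150, 250:400]
        np.testing.assert_allclose(split_post[away], whole.posterior[away],
                                   atol=0.05)


def fake_decoding(states, chrom="chr1", start=0, species=("hg", "sp")):
    n = len(states)
    cols = np.zeros((len(species), n), dtype=np.int8)
    block = block_from_columns(list(species), cols, chrom=chrom, start=start)
    vit = np.array([s == "c" for s in states])
    return BlockDecoding(block, np.where(vit, 0.9, 0.1), vit, 0.0, 0.0, 0.0)


class TestCallElements:
    def test_run_extraction(self):
        dec = fake_decoding("nnncccccnn", start=100)
        (elem,) = call_elements([dec])
        assert (elem.interval.start, elem.interval.end) == (103, 108)

    def test_all_neutral_empty(self):
        assert call_elements([fake_decoding("nnnn")]) == []

    def test_single_neutral_column_separates_runs(self):
        elems = call_elements([fake_decoding("ccnccc", start=0)])
        assert [(e.interval.start, e.interval.end) for e in elems] == [
            (0, 2), (3, 6)
        ]

    def test_adjacent_blocks_merge(self):
        d1 = fake_decoding("nnccc", start=0)
        d2 = fake_decoding("ccnnn", start=5)
        (elem,) = call_elements([d1, d2])
        assert (elem.interval.start, elem.interval.end) == (2, 7)

    def test_insertion_columns_produce_no_coordinates(self):
        rows = [
            MafRow("hg", "chr1", 10, 3, "+", 100, "A--GT"),
            MafRow("sp", "chr1", 0, 5, "+", 100, "ACCGT"),
        ]
        block = AlignmentBlock(rows)
        vit = np.array([True] * 5)
        dec = BlockDecoding(block, np.full(5, 0.9), vit, 0.0, 0.0, 0.0)
        (elem,) = call_elements([dec])
        assert (elem.interval.start, elem.interval.end) == (10, 13)

    def test_expected_element_length_near_target(self, pm16):
        # long simulation: Viterbi segment lengths on conserved tracts
        # should be in the neighbourhood of the expected-length parameter
        rng = np.random.default_rng(321)
        params = ConservationParams()
        mu, nu = hmm_params(params.expected_length, params.target_coverage)
        n = 20_000
        state = np.empty(n, dtype=bool)
        state[0] = rng.random() < params.target_coverage
        r = rng.random(n)
        for t in range(1, n):
            state[t] = (r[t] > mu) if state[t - 1] else (r[t] < nu)
        species = pm16.tree.leaf_names
        cols = np.empty((len(species), n), dtype=np.int8)
        n_cons = int(state.sum())
        _, cons = sample_columns(pm16, n_cons, rng, BranchScaling(s=params.rho))
        _, neut = sample_columns(pm16, n - n_cons, rng)
        cols[:, state] = cons
        cols[:, ~state] = neut
        dec = decode_block(block_from_columns(species, cols), pm16, params)
        elems = call_elements([dec])
        mean_len = np.mean([e.interval.length for e in elems])
        # Viterbi smoothing biases called lengths upward (short gaps are
        # bridged and sub-resolution elements dropped), so the called mean
        # sits somewhat above the nominal expected length, never below it
        # by much and never wildly above.
        assert 0.75 * params.expected_length <= mean_len <= 1.4 * params.expected_length
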