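"""Markov-chain core: construction, stationarity, probabilities, spectra, blocks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markent import markov
from markent.exceptions import (
    DegenerateChainError,
    DegenerateSpectrumError,
    InsufficientDataError,
    InvalidParameterError,
)

from conftest import random_stochastic_matrix


class TestConstruction:
    def test_binary_chain_layout(self):
        m = markov.make_binary_chain(0.9, 0.8)
        np.testing.assert_allclose(m.transitions, [[0.9, 0.1], [0.2, 0.8]])

    def test_iid_chain(self):
        m = markov.make_binary_chain(0.5, 0.5)
        np.testing.assert_allclose(m.transitions, 0.25 * np.ones((2, 2)) + 0.25)

    def test_rows_sum_to_one_exactly(self):
        m = markov.make_binary_chain(0.99, 0.01)
        np.testing.assert_array_equal(m.transitions.sum(axis=1), [1.0, 1.0])

    @pytest.mark.parametrize("p00,p11", [(0.0, 0.5), (1.0, 0.5), (0.5, -0.1), (0.5, 1.5)])
    def test_rejects_out_of_range(self, p00, p11):
        with pytest.raises(InvalidParameterError):
            markov.make_binary_chain(p00, p11)

    def test_rejects_non_stochastic_matrix(self):
        with pytest.raises(InvalidParameterError):
            markov.TransitionModel(np.array([[0.5, 0.4], [0.5, 0.5]]))


class TestStationary:
    def test_binary_closed_form(self):
        pi = markov.stationary_distribution(markov.make_binary_chain(0.9, 0.8))
        np.testing.assert_allclose(pi, [2 / 3, 1 / 3], atol=1e-12)

    @pytest.mark.parametrize("q", [0.1, 0.37, 0.9])
    def test_symmetric_chain_is_uniform(self, q):
        pi = markov.stationary_distribution(markov.make_binary_chain(q, q))
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_doubly_stochastic_uniform(self):
        m = markov.TransitionModel(np.full((4, 4), 0.25))
        np.testing.assert_allclose(markov.stationary_distribution(m), np.full(4, 0.25), atol=1e-12)

    def test_closed_form_on_full_grid(self):
        # p(0) = (1 - p11) / (2 - p00 - p11), on the standard 50x50 lattice
        grid = 0.01 + 0.02 * np.arange(50)
        for p00 in grid:
            for p11 in grid:
                pi = markov.stationary_distribution(markov.make_binary_chain(p00, p11))
                expected = (1.0 - p11) / (2.0 - p00 - p11)
                assert abs(pi[0] - expected) < 1e-12

    @given(st.integers(2, 6), st.integers(0, 2**32 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_stationarity_residual(self, L, seed):
        m = random_stochastic_matrix(L, np.random.default_rng(seed))
        pi = markov.stationary_distribution(m)
        assert np.max(np.abs(pi @ m.transitions - pi)) < 1e-10
        assert abs(pi.sum() - 1.0) < 1e-12

    def test_periodic_chain_is_degenerate(self):
        m = markov.TransitionModel(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(DegenerateChainError):
            markov.stationary_distribution(m)


class TestTrueEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [([0.5, 0.5], math.log(2)), ([1.0, 0.0], 0.0), ([2 / 3, 1 / 3], 0.6365141682948128)],
    )
    def test_values(self, p, expected):
        assert markov.true_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_log_alphabet(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            assert 0.0 <= markov.true_entropy(p) <= math.log(5) + 1e-12


class TestSimulate:
    def test_deterministic_chain_stays_put(self):
        m = markov.TransitionModel(np.eye(2))
        s = markov.simulate(m, 50, initial=[1.0, 0.0], seed=0)
        assert (s == 0).all()

    def test_seed_reproducibility(self, lazy_chain):
        a = markov.simulate(lazy_chain, 500, seed=42)
        b = markov.simulate(lazy_chain, 500, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, markov.simulate(lazy_chain, 500, seed=43))

    def test_length_one_matches_initial_distribution(self, lazy_chain):
        # chi-square test of 1e5 single draws against the initial vector
        from scipy.stats import chisquare

        draws = markov.simulate_batch(lazy_chain, 1, 10**5, initial=[0.25, 0.75], seed=7)
        counts = np.bincount(draws[:, 0], minlength=2)
        assert chisquare(counts, [0.25e5, 0.75e5]).pvalue > 1e-4

    def test_iid_bigram_frequencies(self):
        m = markov.make_binary_chain(0.5, 0.5)
        s = markov.simulate(m, 10**5, seed=11)
        pairs = np.bincount(2 * s[:-1] + s[1:], minlength=4) / (s.size - 1)
        sigma = math.sqrt(0.25 * 0.75 / (s.size - 1))
        assert np.max(np.abs(pairs - 0.25)) < 3 * sigma

    def test_batch_matches_single_marginals(self, lazy_chain):
        seqs = markov.simulate_batch(lazy_chain, 10, 2000, seed=3)
        assert seqs.shape == (2000, 10)
        freq0 = (seqs == 0).mean()
        assert abs(freq0 - 2 / 3) < 0.03


class TestSequenceProbability:
    def test_iid_uniform(self):
        m = markov.make_binary_chain(0.5, 0.5)
        assert markov.sequence_probability(m, [0, 1, 1, 0, 1]) == pytest.approx(2.0**-5)

    def test_hand_product(self, lazy_chain):
        # stationary pi0 = 2/3, then 0->0 (0.9) and 0->1 (0.1)
        assert markov.sequence_probability(lazy_chain, [0, 0, 1]) == pytest.approx(0.06)

    @pytest.mark.parametrize("N", [1, 4, 8, 12])
    def test_normalization(self, lazy_chain, N):
        total = math.fsum(
            markov.sequence_probability(lazy_chain, np.array(s))
            for s in itertools.product(range(2), repeat=N)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestEstimateTransitions:
    def test_bigram_tally(self):
        model, keep = markov.estimate_transitions([0, 0, 1, 1, 0, 0, 1, 1], 2)
        np.testing.assert_array_equal(keep, [0, 1])
        np.testing.assert_allclose(model.transitions, [[0.5, 0.5], [1 / 3, 2 / 3]])

    def test_single_observed_state(self):
        model, keep = markov.estimate_transitions([0, 0, 0, 0], 2)
        np.testing.assert_array_equal(keep, [0])
        np.testing.assert_array_equal(model.transitions, [[1.0]])

    def test_cascading_reduction_fails_cleanly(self):
        with pytest.raises(InsufficientDataError):
            markov.estimate_transitions([0, 1], 2)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            markov.estimate_transitions([0], 2)

    def test_consistency_long_chain(self, lazy_chain):
        s = markov.simulate(lazy_chain, 10**5, seed=5)
        model, keep = markov.estimate_transitions(s, 2)
        np.testing.assert_array_equal(keep, [0, 1])
        for i in range(2):
            n_i = (s[:-1] == i).sum()
            for j in range(2):
                p = lazy_chain.transitions[i, j]
                sigma = math.sqrt(p * (1 - p) / n_i)
                assert abs(model.transitions[i, j] - p) < 3 * sigma


class TestSpectral:
    def test_memory_term_zero_for_independent_chain(self):
        m = markov.make_binary_chain(0.3, 0.7)  # equal rows
        for lag in (1, 2, 5, 10):
            assert markov.memory_term(m, lag) == pytest.approx(0.0, abs=1e-12)

    def test_memory_term_hand_value(self, lazy_chain):
        assert markov.memory_term(lazy_chain, 2) == pytest.approx(0.49, abs=1e-12)

    @pytest.mark.parametrize("p00,p11", [(0.9, 0.8), (0.2, 0.6), (0.55, 0.45)])
    def test_binary_trace_identity(self, p00, p11):
        m = markov.make_binary_chain(p00, p11)
        for lag in (1, 2, 3, 7):
            assert markov.memory_term(m, lag) == pytest.approx((p00 + p11 - 1) ** lag, abs=1e-12)

    @given(st.integers(2, 6), st.integers(1, 8), st.integers(0, 2**32 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_spectral_identity(self, L, lag, seed):
        m = random_stochastic_matrix(L, np.random.default_rng(seed))
        lam = np.sort_complex(m.eigenvalues())
        unit = np.argmin(np.abs(lam - 1.0))
        rest = np.delete(lam, unit)
        assert abs(markov.memory_term(m, lag) - (rest**lag).sum().real) < 1e-9

    def test_spectral_correction_binary(self, lazy_chain):
        assert markov.spectral_correction(lazy_chain) == pytest.approx(0.7 / 0.3, abs=1e-12)

    def test_spectral_correction_independent_chain(self):
        assert markov.spectral_correction(markov.make_binary_chain(0.4, 0.6)) == pytest.approx(0.0, abs=1e-12)

    def test_cyclic_permutation_degenerate(self):
        m = markov.TransitionModel(np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float))
        with pytest.raises(DegenerateSpectrumError):
            markov.spectral_correction(m)
        assert markov.spectrum_summary(m).degenerate


class TestBlocks:
    def test_block_chain_n1_is_bernoulli(self):
        m = markov.block_chain(0.3, 1)
        np.testing.assert_allclose(m.transitions, [[0.7, 0.3], [0.7, 0.3]])

    def test_block_chain_shift_rule(self):
        m = markov.block_chain(0.3, 2)
        np.testing.assert_allclose(m.transitions[1], [0, 0, 0.7, 0.3])
        assert (np.count_nonzero(m.transitions, axis=1) == 2).all()

    @pytest.mark.parametrize("n,p", [(1, 0.3), (3, 0.1), (6, 0.45)])
    def test_product_bernoulli_is_stationary(self, n, p):
        m = markov.block_chain(p, n)
        pi = markov.block_stationary(p, n)
        assert abs(pi.sum() - 1.0) < 1e-12
        assert np.max(np.abs(pi @ m.transitions - pi)) < 1e-12

    def test_complement_symmetry(self):
        # flipping every bit maps the p-chain onto the (1-p)-chain
        n, p = 3, 0.2
        a = markov.block_chain(p, n).transitions
        b = markov.block_chain(1 - p, n).transitions
        flip = (2**n - 1) - np.arange(2**n)
        np.testing.assert_allclose(a, b[np.ix_(flip, flip)], atol=1e-15)

    def test_encode_example(self):
        np.testing.assert_array_equal(markov.encode_blocks([0, 1, 1, 0], 2), [1, 3, 2])

    def test_encode_identity_for_n1(self, rng):
        s = rng.integers(0, 2, 30)
        np.testing.assert_array_equal(markov.encode_blocks(s, 1), s)

    @given(st.lists(st.integers(0, 1), min_size=4, max_size=40), st.integers(1, 4))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_shift_identity(self, bits, n):
        if len(bits) < n + 1:
            bits = bits + [0] * (n + 1 - len(bits))
        z = markov.encode_blocks(np.array(bits), n)
        s = np.array(bits)
        expected = (2 * z[:-1]) % (2**n) + s[n:]
        np.testing.assert_array_equal(z[1:], expected)

    def test_encode_too_short(self):
        with pytest.raises(InsufficientDataError):
            markov.encode_blocks([0, 1], 3)

    @pytest.mark.parametrize(
        "p,n,expected",
        [(0.5, 6, 6 * math.log(2)), (0.5, 1, math.log(2))],
    )
    def test_iid_block_entropy_values(self, p, n, expected):
        assert markov.iid_block_entropy(p, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p,n", [(0.1, 4), (0.37, 5)])
    def test_iid_block_entropy_equals_brute_force(self, p, n):
        brute = markov.true_entropy(markov.block_stationary(p, n))
        assert markov.iid_block_entropy(p, n) == pytest.approx(brute, abs=1e-10)

    @pytest.mark.parametrize("n,n_blocks", [(1, 4), (2, 5), (3, 6)])
    def test_block_dynamics_equivalence(self, n, n_blocks):
        """Sliding-window encoding of i.i.d. bits and the shift chain give the
        same exact distribution over window-state sequences."""
        p = 0.37
        n_bits = n_blocks + n - 1
        chain = markov.block_chain(p, n)
        init = markov.block_stationary(p, n)
        dist: dict[tuple, float] = {}
        for bits in itertools.product((0, 1), repeat=n_bits):
            prob = math.prod(p if b else 1.0 - p for b in bits)
            key = tuple(markov.encode_blocks(np.array(bits), n))
            dist[key] = dist.get(key, 0.0) + prob
        chain_mass = 0.0
        for key, prob in dist.items():
            q = markov.sequence_probability(chain, np.array(key), initial=init)
            assert abs(q - prob) < 1e-12
            chain_mass += q
        # the chain puts all its mass on the shift-consistent sequences,
        # so agreement on this support is agreement everywhere
        assert chain_mass == pytest.approx(1.0, abs=1e-12)

    def test_n_block_sequences(self):
        assert markov.n_block_sequences(2, 3) == 64
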