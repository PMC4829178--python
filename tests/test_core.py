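"""Unit and property tests for the observer's inference machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numbayes import (
    DEFAULT_SUPPORT,
    ObserverSpec,
    PriorState,
    SupportGrid,
    apply_response_noise,
    compute_posterior,
    decide,
    dirichlet_update,
    kernel_update,
    likelihood_over_support,
    softmax_transform,
    supermodel_response,
)
from numbayes.core import kernel_increment, round_half_up
from scipy.stats import chisquare


class TestLikelihood:
    def test_lognormal_ratio_at_fixed_distance(self):
        # exp(-(log(29/23))^2 / (2*0.22^2)) ~= 0.574
        L = likelihood_over_support(23.0, 0.22)
        ratio = L[DEFAULT_SUPPORT.index(29)] / L[DEFAULT_SUPPORT.index(23)]
        assert ratio == pytest.approx(0.574, abs=1e-3)

    def test_vanishing_noise_concentrates_on_true_value(self):
        L = likelihood_over_support(23.0, 1e-6)
        assert L[DEFAULT_SUPPORT.index(23)] / L.sum() > 1 - 1e-9

    def test_unimodal_with_max_at_internal_estimate(self):
        L = likelihood_over_support(23.0, 0.22)
        assert DEFAULT_SUPPORT.values[np.argmax(L)] == 23
        # brute-force unimodality scan over all 100 entries
        peak = np.argmax(L)
        assert np.all(np.diff(L[: peak + 1]) > 0)
        assert np.all(np.diff(L[peak:]) < 0)

    @pytest.mark.parametrize("X,sigma", [(-1.0, 0.2), (0.0, 0.2), (23.0, 0.0), (23.0, -1.0)])
    def test_invalid_arguments_rejected(self, X, sigma):
        with pytest.raises(ValueError):
            likelihood_over_support(X, sigma)


class TestPosterior:
    def test_flat_prior_returns_normalized_likelihood(self):
        prior = np.full(100, 0.01)
        post = compute_posterior(prior, 26.0, 0.22)
        L = likelihood_over_support(26.0, 0.22)
        np.testing.assert_allclose(post, L / L.sum(), rtol=1e-12)

    def test_point_mass_prior_dominates(self):
        prior = np.zeros(100)
        prior[DEFAULT_SUPPORT.index(25)] = 1.0
        for X in (5.0, 25.0, 80.0):
            post = compute_posterior(prior, X, 0.22)
            assert post[DEFAULT_SUPPORT.index(25)] == pytest.approx(1.0)

    def test_bimodal_prior_yields_bimodal_posterior(self):
        # brute-force oracle on the 7-point narrow support
        support = SupportGrid(23, 29)
        prior = np.array([0.3, 0.08, 0.08, 0.08, 0.08, 0.08, 0.3])
        oracle = np.exp(-(np.log(26.0) - np.log(support.values)) ** 2 / (2 * 0.22**2))
        oracle = oracle * prior
        oracle /= oracle.sum()
        post = compute_posterior(prior, 26.0, 0.22, support)
        np.testing.assert_allclose(post, oracle, rtol=1e-10)
        assert post[0] > post[1] and post[6] > post[5]  # peaks at 23 and 29

    def test_normalization_invariant(self):
        prior = np.random.default_rng(0).dirichlet(np.ones(100))
        for X in (3.0, 26.0, 99.0):
            assert compute_posterior(prior, X, 0.3).sum() == pytest.approx(1.0, abs=1e-12)


class TestPriorUpdates:
    def test_dirichlet_increments_feedback_entry(self):
        support = SupportGrid(1, 3)
        state = PriorState(np.ones(3), support)
        new = dirichlet_update(state, 2)
        np.testing.assert_array_equal(new.alpha, [1.0, 2.0, 1.0])

    def test_update_conserves_unit_mass(self):
        state = PriorState.uniform()
        for fb in (1, 26, 100):
            assert dirichlet_update(state, fb).alpha.sum() == state.alpha.sum() + 1
            assert kernel_update(state, fb, 2.0).alpha.sum() == pytest.approx(
                state.alpha.sum() + 1, abs=1e-9
            )

    def test_feedback_outside_support_rejected(self):
        state = PriorState.uniform()
        with pytest.raises(ValueError):
            dirichlet_update(state, 101)
        with pytest.raises(ValueError):
            kernel_update(state, 0, 1.0)

    def test_kernel_with_zero_width_equals_dirichlet(self):
        state = PriorState.uniform()
        np.testing.assert_array_equal(
            kernel_update(state, 26, 0.0).alpha, dirichlet_update(state, 26).alpha
        )

    def test_kernel_increment_symmetric_and_peaked(self):
        delta = kernel_increment(26, 1.0)
        i = DEFAULT_SUPPORT.index(26)
        assert delta[i] > delta[i - 1] == pytest.approx(delta[i + 1], rel=1e-9)
        assert delta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_huge_kernel_width_is_uniform(self):
        delta = kernel_increment(26, 1000.0)
        assert np.all(np.abs(delta - 0.01) < 1e-3)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            kernel_increment(26, -0.1)

    def test_dirichlet_learning_converges_to_training_distribution(self, narrow):
        # law of large numbers: predictive prior approaches the narrow design
        rng = np.random.default_rng(5)
        errs = []
        target = narrow.pmf_on(DEFAULT_SUPPORT)
        for _ in range(20):
            state = PriorState.uniform()
            draws = rng.choice(narrow.values, size=300, p=narrow.probs)
            for d in draws:
                state = dirichlet_update(state, int(d))
            errs.append(np.abs(state.predictive() - target).sum())
        # 100 uniform pseudo-counts against 300 observations leave ~2*100/400
        # of the mass misplaced; sampling noise adds a little more
        assert np.mean(errs) < 0.65
        # and with the pseudo-counts subtracted the counts match closely
        state = PriorState.uniform()
        draws = rng.choice(narrow.values, size=3000, p=narrow.probs)
        for d in draws:
            state = dirichlet_update(state, int(d))
        emp = (state.alpha - 1) / 3000
        assert np.abs(emp - target).sum() < 0.1


class TestSoftmax:
    def test_unit_exponent_is_identity(self):
        p = np.array([0.5, 0.25, 0.25])
        np.testing.assert_allclose(softmax_transform(p, 1.0), p)

    def test_hand_computed_three_entry_case(self):
        np.testing.assert_allclose(
            softmax_transform(np.array([0.5, 0.25, 0.25]), 2.0),
            [2 / 3, 1 / 6, 1 / 6],
            rtol=1e-12,
        )

    def test_large_exponent_concentrates_on_map(self):
        p = np.array([0.1, 0.7, 0.2])
        assert softmax_transform(p, 1000.0)[1] > 1 - 1e-6

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            softmax_transform(np.array([0.5, 0.5]), 0.0)

    @given(
        probs=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=10),
        beta=st.floats(0.1, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_preserved_for_all_positive_exponents(self, probs, beta):
        p = np.array(probs) / np.sum(probs)
        q = softmax_transform(p, beta)
        assert np.all(np.argsort(p, kind="stable") == np.argsort(q, kind="stable"))

    def test_map_mass_monotone_in_exponent(self):
        p = np.random.default_rng(3).dirichlet(np.ones(20))
        masses = [softmax_transform(p, b).max() for b in (0.5, 1, 2, 4, 8, 50)]
        assert np.all(np.diff(masses) >= 0)


class TestDecisions:
    def test_mean_of_uniform_posterior_is_midpoint(self):
        support = SupportGrid(23, 29)
        assert decide(np.full(7, 1 / 7), "mean", support=support) == 26

    def test_max_picks_largest_entry(self):
        support = SupportGrid(23, 25)
        assert decide(np.array([0.1, 0.7, 0.2]), "max", support=support) == 24

    def test_max_tie_breaks_to_smallest_index(self):
        support = SupportGrid(23, 25)
        assert decide(np.array([0.45, 0.45, 0.1]), "max", support=support) == 23

    def test_sampling_matches_posterior_pmf(self, rng):
        support = SupportGrid(23, 29)
        p = np.array([0.3, 0.08, 0.08, 0.08, 0.08, 0.08, 0.3])
        draws = rng.choice(support.values, size=100_000, p=p)
        counts = np.array([(draws == v).sum() for v in support.values])
        assert chisquare(counts, p * 100_000).pvalue > 0.01

    def test_round_half_up(self):
        assert round_half_up(25.5) == 26
        assert round_half_up(26.4999) == 26
        assert round_half_up(np.array([1.5, 2.5])).tolist() == [2, 3]


class TestSupermodel:
    def test_single_sample_reproduces_posterior(self, rng):
        support = SupportGrid(23, 29)
        p = np.array([0.3, 0.08, 0.08, 0.08, 0.08, 0.08, 0.3])
        draws = [supermodel_response(p, 1, 1.0, rng, support) for _ in range(50_000)]
        counts = np.array([(np.array(draws) == v).sum() for v in support.values])
        assert chisquare(counts, p * 50_000).pvalue > 0.01

    def test_many_samples_approximate_mean_decision(self, rng):
        support = SupportGrid(23, 29)
        p = np.array([0.3, 0.08, 0.08, 0.08, 0.08, 0.08, 0.3])
        mean_resp = decide(p, "mean", support=support)
        draws = [supermodel_response(p, 10_000, 1.0, rng, support) for _ in range(100)]
        assert np.mean(np.array(draws) == mean_resp) >= 0.99

    def test_large_exponent_reproduces_map(self, rng):
        support = SupportGrid(23, 29)
        p = np.array([0.35, 0.08, 0.08, 0.08, 0.08, 0.08, 0.25])
        draws = [supermodel_response(p, 3, 1000.0, rng, support) for _ in range(2000)]
        assert np.mean(np.array(draws) == 23) > 1 - 1e-3


class TestResponseNoise:
    def test_zero_rate_is_identity(self, rng):
        spec = ObserverSpec(sigma=0.2, noise="trembling", epsilon=0.0)
        assert all(apply_response_noise(23, spec, rng) == 23 for _ in range(100))

    def test_full_rate_is_uniform(self, rng):
        spec = ObserverSpec(sigma=0.2, noise="trembling", epsilon=1.0)
        draws = np.array([apply_response_noise(23, spec, rng) for _ in range(100_000)])
        counts = np.bincount(draws - 1, minlength=100)
        assert chisquare(counts).pvalue > 0.01

    def test_partial_rate_mixture_fraction(self, rng):
        spec = ObserverSpec(sigma=0.2, noise="trembling", epsilon=0.05)
        draws = np.array([apply_response_noise(23, spec, rng) for _ in range(100_000)])
        frac_changed = np.mean(draws != 23)
        assert frac_changed == pytest.approx(0.05 * 99 / 100, abs=0.003)
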