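"""Elementary model operations: logit-linear affinities, the unified DDA,
the balancing constant delta, presence likelihood, and the joint density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from ddaffinity import (
    compute_delta,
    dda_from_design,
    log_joint_density,
    presence_likelihood,
    unified_dda,
)
from ddaffinity.model import PriorSpec

probs = st.floats(min_value=1e-4, max_value=1 - 1e-4)


class TestDdaFromDesign:
    def test_neutral_inputs_give_half(self):
        assert dda_from_design(np.zeros(3), 0.0, np.zeros(3)) == pytest.approx(0.5)

    def test_intercept_only_closed_form(self):
        assert dda_from_design(np.empty(0), np.log(3), np.empty(0)) == pytest.approx(0.75)

    def test_single_negative_coefficient(self):
        # a trait value of 0.5 under slope -4.7 puts the affinity at logit^-1(-2.35)
        assert dda_from_design(np.array([0.5]), 0.0, np.array([-4.7])) == pytest.approx(
            0.0871, abs=5e-5
        )

    def test_length_mismatch_is_contract_error(self):
        with pytest.raises(ValueError, match="columns"):
            dda_from_design(np.zeros(2), 0.0, np.zeros(3))


class TestUnifiedDda:
    @pytest.mark.parametrize(
        "sp, site, expected",
        [(0.5, 0.5, 0.5), (0.8, 0.8, 0.8), (0.9, 0.5, 0.75)],
    )
    def test_worked_values(self, sp, site, expected):
        assert unified_dda(sp, site) == pytest.approx(expected, abs=1e-9)

    @given(probs, probs)
    @settings(deadline=None)
    def test_geometric_mean_of_odds_identity(self, a, b):
        dda = unified_dda(a, b)
        odds = dda / (1 - dda)
        geo = np.sqrt((a / (1 - a)) * (b / (1 - b)))
        assert odds == pytest.approx(geo, rel=1e-9)

    @given(probs, probs)
    @settings(deadline=None)
    def test_symmetric(self, a, b):
        assert unified_dda(a, b) == pytest.approx(unified_dda(b, a), abs=1e-12)

    @given(probs, probs, probs)
    @settings(deadline=None)
    def test_strictly_increasing_in_each_argument(self, a, b, c):
        lo, hi = sorted({a, c})[0], sorted({a, c})[-1]
        if lo < hi:
            assert unified_dda(lo, b) < unified_dda(hi, b)

    def test_boundary_inputs_are_clamped_not_nan(self):
        out = unified_dda(0.0, 1.0, eps=1e-6)
        assert 0.0 < out < 1.0


class TestDelta:
    def test_zero_when_half_prevalence_and_full_suit(self):
        assert compute_delta(np.array([1, 0, 1, 0]), np.ones(4)) == pytest.approx(0.0)

    def test_ln_three_case(self):
        prab = np.array([1, 0, 1, 0])
        suit = np.full(4, 0.5)
        assert compute_delta(prab, suit) == pytest.approx(np.log(3), abs=1e-12)

    @pytest.mark.parametrize("prab", [np.zeros(4), np.ones(4)])
    def test_degenerate_prevalence_errors(self, prab):
        with pytest.raises(ValueError, match="undefined"):
            compute_delta(prab, np.full(4, 0.5))


class TestPresenceLikelihood:
    @pytest.mark.parametrize(
        "dda, suit, delta, expected",
        [(0.5, 1.0, 0.0, 0.5), (0.75, 1.0, 0.0, 0.25)],
    )
    def test_worked_values(self, dda, suit, delta, expected):
        assert presence_likelihood(dda, suit, delta) == pytest.approx(expected, abs=1e-12)

    def test_zero_suitability_hits_clamp_floor(self):
        out = presence_likelihood(0.3, 0.0, 0.0, eps=1e-6)
        assert out == pytest.approx(1e-6, rel=1e-3)

    @given(probs, probs, st.floats(min_value=-3, max_value=3))
    @settings(deadline=None)
    def test_stays_in_open_interval(self, dda, suit, delta):
        assert 0.0 < presence_likelihood(dda, suit, delta) < 1.0


class TestBalancingIdentity:
    def test_neutral_dda_constant_suit_gives_observed_prevalence(self, rng):
        """DDA == 0.5 everywhere with constant suit makes p the prevalence, exactly."""
        prab = (rng.random((12, 9)) < 0.4).astype(float)
        if not 0 < prab.mean() < 1:
            prab[0, 0] = 1 - prab[0, 0]
        suit = np.full_like(prab, 0.6)
        delta = compute_delta(prab, suit)
        p = presence_likelihood(np.full_like(prab, 0.5), suit, delta)
        np.testing.assert_allclose(p, prab.mean(), atol=1e-12)


class TestLogJointDensity:
    def _data(self, rng, S=6, T=5, k_sp=2, k_site=1):
        prab = (rng.random((S, T)) < 0.5).astype(float)
        suit = rng.uniform(0.1, 0.9, (S, T))
        X = rng.standard_normal((S, k_sp))
        E = rng.standard_normal((T, k_site))
        return prab, suit, X, E

    def test_closed_form_assembly_at_the_prior_mode(self, rng):
        S, T = 4, 4
        prab = np.array([[1, 0, 1, 0]] * S, dtype=float)
        suit = np.full((S, T), 0.5)
        X = np.empty((S, 0))
        E = np.empty((T, 0))
        delta = compute_delta(prab, suit)
        value = log_joint_density(np.zeros(2), prab, suit, X, E, delta)
        # all coefficients 0 -> DDA = 0.5 -> p = prevalence = 0.5 per cell
        priors_at_mode = 2 * (-np.log(0.5 * np.sqrt(2 * np.pi)))
        expected = priors_at_mode + prab.size * np.log(0.5)
        assert value == pytest.approx(expected, abs=1e-10)

    def test_finite_difference_matches_hand_derived_gradient(self, rng):
        """Chain-rule gradient of the composed density, derived independently."""
        prab, suit, X, E = self._data(rng)
        delta = compute_delta(prab, suit)
        theta = 0.3 * rng.standard_normal(2 + X.shape[1] + E.shape[1])
        a_sp, a_site = theta[0], theta[1]
        b_sp = theta[2 : 2 + X.shape[1]]
        b_site = theta[2 + X.shape[1] :]

        eta_sp = a_sp + X @ b_sp
        eta_site = a_site + E @ b_site
        dda = expit(0.5 * (eta_sp[:, None] + eta_site[None, :]))
        q = (1 - dda) * suit  # no clamp active at these moderate values
        p = expit(logit(q) + delta)
        # d loglik / d logit(dda) per cell
        core = (prab - p) / (q * (1 - q)) * (-suit) * dda * (1 - dda) * 0.5
        grad = np.concatenate(
            [
                [core.sum() - a_sp / 0.5**2],
                [core.sum() - a_site / 0.5**2],
                X.T @ core.sum(axis=1) - b_sp / 2.5**2,
                E.T @ core.sum(axis=0) - b_site / 2.5**2,
            ]
        )

        def f(t):
            return log_joint_density(t, prab, suit, X, E, delta)

        h = 1e-6
        for k in range(theta.size):
            e = np.zeros_like(theta)
            e[k] = h
            num = (f(theta + e) - f(theta - e)) / (2 * h)
            assert num == pytest.approx(grad[k], rel=1e-5, abs=1e-7)

    def test_empty_matrix_reduces_to_prior(self):
        prab = np.empty((0, 0))
        suit = np.empty((0, 0))
        X = np.empty((0, 0))
        E = np.empty((0, 0))
        theta = np.array([0.2, -0.1])
        value = log_joint_density(theta, prab, suit, X, E, delta=0.0)
        priors = PriorSpec()
        expected = sum(
            -0.5 * (t / priors.scale_a) ** 2 - np.log(priors.scale_a * np.sqrt(2 * np.pi))
            for t in theta
        )
        assert value == pytest.approx(expected, abs=1e-12)

    def test_parameter_count_enforced(self, rng):
        prab, suit, X, E = self._data(rng)
        with pytest.raises(ValueError, match="parameters"):
            log_joint_density(np.zeros(99), prab, suit, X, E, delta=0.0)

    def test_shared_intercept_ties_both_sides(self, rng):
        prab, suit, X, E = self._data(rng)
        delta = compute_delta(prab, suit)
        k = X.shape[1] + E.shape[1]
        theta_shared = np.concatenate([[0.4], 0.1 * np.ones(k)])
        theta_split = np.concatenate([[0.4, 0.4], 0.1 * np.ones(k)])
        shared = log_joint_density(theta_shared, prab, suit, X, E, delta, shared_intercept=True)
        split = log_joint_density(theta_split, prab, suit, X, E, delta)
        # likelihoods agree; only the prior differs by one intercept term
        prior_extra = -0.5 * (0.4 / 0.5) ** 2 - np.log(0.5 * np.sqrt(2 * np.pi))
        assert shared == pytest.approx(split - prior_extra, abs=1e-10)
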