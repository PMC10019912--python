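"""Links, complete-data likelihood, and the exhaustive marginal oracle."""

import numpy as np
import pytest
from scipy.special import expit, logsumexp
from scipy.stats import binom, poisson

from cbctrends.dmm import (
    complete_data_loglik,
    covariate_design,
    linear_predictors,
    marginal_loglik_bruteforce,
)
from cbctrends.types import DMMParams, LatentState
from tests.conftest import make_panel


class TestLinearPredictors:
    def _zero_design(self, n=3, T=4):
        panel = make_panel(np.zeros((n, T)))
        return covariate_design(panel)

    def test_link_identities_at_zero(self):
        d = self._zero_design()
        params = DMMParams(beta_lambda=np.zeros(5), beta_omega=np.zeros(5),
                           beta_gamma=np.zeros(5), alpha0=0.0, a_e=1.0, a_m=-1.0)
        lam, omega, gamma, p = linear_predictors(params, d["Z"], d["effort_z"],
                                                 d["temp_z"], check=False)
        np.testing.assert_allclose(lam, 1.0)
        np.testing.assert_allclose(omega, 0.5)
        np.testing.assert_allclose(gamma, 1.0)
        np.testing.assert_allclose(p, 0.5)

    def test_detection_scalar_arithmetic(self):
        """p(effort=1, temp=-1 | alpha0=0, a_e=0.5, a_m=-0.5) = logistic(1)."""
        d = self._zero_design()
        params = DMMParams(beta_lambda=np.zeros(5), beta_omega=np.zeros(5),
                           beta_gamma=np.zeros(5), alpha0=0.0, a_e=0.5, a_m=-0.5)
        _, _, _, p = linear_predictors(params, d["Z"],
                                       np.ones_like(d["effort_z"]),
                                       -np.ones_like(d["temp_z"]), check=False)
        np.testing.assert_allclose(p, expit(1.0))
        assert abs(p.flat[0] - 0.7311) < 1e-4

    def test_detection_monotone_in_effort_limit(self):
        d = self._zero_design()
        params = DMMParams(beta_lambda=np.zeros(5), beta_omega=np.zeros(5),
                           beta_gamma=np.zeros(5), alpha0=0.0, a_e=0.5, a_m=-0.5)
        _, _, _, p = linear_predictors(params, d["Z"],
                                       np.full_like(d["effort_z"], 50.0),
                                       d["temp_z"], check=False)
        assert np.all(p > 0.999999)

    def test_unstandardized_covariates_warn(self):
        panel = make_panel(np.zeros((3, 4)))
        d = covariate_design(panel)
        params = DMMParams(beta_lambda=np.zeros(5), beta_omega=np.zeros(5),
                           beta_gamma=np.zeros(5), alpha0=0.0, a_e=1.0, a_m=-1.0)
        with pytest.warns(UserWarning, match="standardized"):
            linear_predictors(params, d["Z"], d["effort_z"] + 7.0, d["temp_z"])


class TestRescaleParams:
    def test_predictors_invariant_across_standardizations(self):
        """Rescaled coefficients reproduce the same rates on shared circles."""
        from cbctrends import synthetic as syn
        from cbctrends.dmm import linear_predictors, rescale_params

        cfg = syn.SimulationConfig(n_circles=20, year_start=1999, year_end=2018,
                                   missing_prob_pre1967=0.0,
                                   missing_prob_post1967=0.0, seed=6,
                                   dmm_params=syn.recovery_dmm_params())
        res = syn.simulate(cfg)
        filt, _ = syn.apply_study_filters(res.panel, min_circle_samplings=10)
        d_full = covariate_design(res.panel)
        d_filt = covariate_design(filt)
        p1 = rescale_params(cfg.dmm_params, d_full["scales"], d_filt["scales"])
        keep = np.searchsorted(res.panel.circles, filt.circles)
        a = linear_predictors(cfg.dmm_params, d_full["Z"], d_full["effort_z"],
                              d_full["temp_z"], check=False)
        b = linear_predictors(p1, d_filt["Z"], d_filt["effort_z"],
                              d_filt["temp_z"], check=False)
        np.testing.assert_allclose(a[0][keep], b[0], rtol=1e-10)
        for x, y in zip(a[1:], b[1:]):
            np.testing.assert_allclose(x[keep], y, rtol=1e-10)

    def test_identity_when_scales_match(self, intercept_params):
        from cbctrends.dmm import rescale_params

        scales = {k: (0.0, 1.0) for k in
                  ("elevation", "habitat_area", "developed_area",
                   "human_density", "effort", "min_temp")}
        out = rescale_params(intercept_params, scales, scales)
        np.testing.assert_allclose(out.to_vector(), intercept_params.to_vector())


class TestCompleteDataLoglik:
    def test_perfect_detection_single_site_collapses_to_poisson(self, intercept_params):
        p1 = DMMParams(beta_lambda=intercept_params.beta_lambda,
                       beta_omega=intercept_params.beta_omega,
                       beta_gamma=intercept_params.beta_gamma,
                       alpha0=50.0, a_e=0.5, a_m=-0.5)  # p ~ 1
        X = np.array([[3.0]])
        panel = make_panel(X)
        latent = LatentState(N=np.array([[3]]), S=np.array([[0]]), R=np.array([[0]]))
        ll = complete_data_loglik(p1, latent, panel)
        np.testing.assert_allclose(ll, poisson.logpmf(3, 2.0), atol=1e-9)

    def test_count_exceeding_abundance_is_log_zero(self, intercept_params):
        panel = make_panel(np.array([[5.0]]))
        latent = LatentState(N=np.array([[3]]), S=np.array([[0]]), R=np.array([[0]]))
        assert complete_data_loglik(intercept_params, latent, panel) == -np.inf

    def test_survivors_exceeding_previous_abundance_is_log_zero(self, intercept_params):
        panel = make_panel(np.array([[1.0, 1.0]]))
        latent = LatentState(N=np.array([[1, 3]]), S=np.array([[0, 2]]),
                             R=np.array([[0, 1]]))
        assert complete_data_loglik(intercept_params, latent, panel) == -np.inf

    def test_two_site_two_year_hand_computation(self, intercept_params):
        """Term-by-term density sum via scipy, all quantities <= 5."""
        X = np.array([[2.0, 2.0], [1.0, 1.0]])
        N = np.array([[2, 3], [1, 1]])
        S = np.array([[0, 1], [0, 1]])
        R = np.array([[0, 2], [0, 0]])
        panel = make_panel(X)
        latent = LatentState(N=N, S=S, R=R)
        lam, om, gm, p = 2.0, 0.6, 0.4, expit(0.5)
        expected = (
            poisson.logpmf(N[:, 0], lam).sum()
            + binom.logpmf(S[:, 1], N[:, 0], om).sum()
            + poisson.logpmf(R[:, 1], gm * N[:, 0]).sum()
            + binom.logpmf(X.astype(int), N, p).sum()
        )
        got = complete_data_loglik(intercept_params, latent, panel)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_missing_counts_contribute_no_observation_term(self, intercept_params):
        X_obs = np.array([[2.0, 1.0]])
        X_miss = np.array([[2.0, np.nan]])
        latent = LatentState(N=np.array([[2, 2]]), S=np.array([[0, 1]]),
                             R=np.array([[0, 1]]))
        ll_obs = complete_data_loglik(intercept_params, latent, make_panel(X_obs))
        ll_miss = complete_data_loglik(intercept_params, latent, make_panel(X_miss))
        p = expit(0.5)
        np.testing.assert_allclose(ll_obs - ll_miss, binom.logpmf(1, 2, p), rtol=1e-10)


class TestBruteForceMarginal:
    def test_poisson_thinning_identity_single_site_year(self, intercept_params):
        """1 site, 1 year: marginal is Poisson(X; Lambda * p) exactly."""
        p = expit(0.5)
        for X in (0, 1, 4):
            panel = make_panel([[float(X)]])
            mll = marginal_loglik_bruteforce(intercept_params, panel, n_max=60)
            np.testing.assert_allclose(mll, poisson.logpmf(X, 2.0 * p), atol=1e-10)

    def test_explicit_sum_matches_closed_form(self, intercept_params):
        """Same identity via the explicit sum over N."""
        p = expit(0.5)
        X = 2
        states = np.arange(61)
        direct = logsumexp(poisson.logpmf(states, 2.0) + binom.logpmf(X, states, p))
        panel = make_panel([[float(X)]])
        np.testing.assert_allclose(
            marginal_loglik_bruteforce(intercept_params, panel, n_max=60),
            direct, atol=1e-10)

    def test_observation_distribution_normalizes(self, intercept_params):
        """Sum over all (X1, X2) grids ~ 1 for Lambda << n_max."""
        total = sum(
            np.exp(marginal_loglik_bruteforce(intercept_params,
                                              make_panel([[float(a), float(b)]]),
                                              n_max=40))
            for a in range(40) for b in range(40)
        )
        assert abs(total - 1.0) < 1e-8

    def test_truncation_convergence(self, intercept_params, rising_panel):
        a = marginal_loglik_bruteforce(intercept_params, rising_panel, n_max=20)
        b = marginal_loglik_bruteforce(intercept_params, rising_panel, n_max=30)
        assert abs(a - b) < 1e-10

    def test_oversized_state_space_refused(self, intercept_params):
        panel = make_panel(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="state space"):
            marginal_loglik_bruteforce(intercept_params, panel, n_max=30,
                                       state_cap=100)
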