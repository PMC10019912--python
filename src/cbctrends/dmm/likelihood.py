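"""Link functions and the complete-data log likelihood of the Dail-Madsen model.

The model for one species over circles i and years t:

    N[i,1] ~ Poisson(Lambda_i1),        log Lambda = Z_lambda . beta_lambda
    S[i,t] | N[i,t-1] ~ Binomial(N[i,t-1], omega_it),   logit omega = Z . beta_omega
    R[i,t] | N[i,t-1] ~ Poisson(gamma_it * N[i,t-1]),   log gamma = Z . beta_gamma
    N[i,t] = S[i,t] + R[i,t]
    X[i,t] | N[i,t] ~ Binomial(N[i,t], p_it),   logit p = alpha0 + a_e*effort + a_m*temp

Covariates are standardized to mean 0, sd 1 before entering any linear
predictor. Rates are clipped after link inversion (omega to
[1e-9, 1 - 1e-9]; gamma and Lambda to [1e-9, inf)) so extreme covariate
draws cannot produce degenerate samplers.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, gammaln, xlog1py, xlogy

from ..types import COVARIATE_NAMES, DMMParams, LatentState, ObservationPanel

OMEGA_EPS = 1e-9
RATE_FLOOR = 1e-9


def clip_prob(x: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, OMEGA_EPS), 1.0 - OMEGA_EPS)


def clip_rate(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, RATE_FLOOR)


def standardize(x: np.ndarray, mask: np.ndarray | None = None):
    """Return ``(z, mean, sd)`` with z-scores computed over ``mask`` entries.

    A constant column gets sd 1 so the z-score is identically zero instead
    of undefined.
    """
    x = np.asarray(x, dtype=float)
    vals = x[mask] if mask is not None else x
    mean = float(np.nanmean(vals))
    sd = float(np.nanstd(vals))
    if sd < 1e-12:
        sd = 1.0
    return (x - mean) / sd, mean, sd


def check_standardized(x: np.ndarray, name: str, tol: float = 0.01) -> None:
    vals = x[np.isfinite(x)]
    if vals.size and (abs(vals.mean()) > tol or abs(vals.std() - 1.0) > tol):
        warnings.warn(
            f"covariate {name!r} does not look standardized "
            f"(mean {vals.mean():.3f}, sd {vals.std():.3f}); linear predictors "
            "assume mean 0, sd 1",
            stacklevel=3,
        )


def covariate_design(panel_like) -> dict[str, np.ndarray]:
    """Standardized design arrays from an :class:`ObservationPanel`.

    Returns ``Z`` of shape (n, T, 5) — intercept plus the four standardized
    site covariates — together with standardized effort and temperature and
    the effort standard deviation (needed to rescale interval widths).
    """
    p = panel_like
    n, T = p.n_circles, p.n_years
    elev_z, elev_m, elev_s = standardize(p.elevation)
    hab_z, hab_m, hab_s = standardize(p.habitat_area)
    dev_z, dev_m, dev_s = standardize(p.developed_area)
    den_z, den_m, den_s = standardize(p.human_density)
    Z = np.empty((n, T, 1 + len(COVARIATE_NAMES)))
    Z[:, :, 0] = 1.0
    Z[:, :, 1] = elev_z[:, None]
    Z[:, :, 2] = hab_z
    Z[:, :, 3] = dev_z
    Z[:, :, 4] = den_z
    obs = p.observed
    eff_z, eff_m, eff_sd = standardize(p.effort, mask=obs if obs.any() else None)
    temp_z, temp_m, temp_s = standardize(p.temp, mask=obs if obs.any() else None)
    scales = {
        "elevation": (elev_m, elev_s),
        "habitat_area": (hab_m, hab_s),
        "developed_area": (dev_m, dev_s),
        "human_density": (den_m, den_s),
        "effort": (eff_m, eff_sd),
        "min_temp": (temp_m, temp_s),
    }
    return {"Z": Z, "effort_z": eff_z, "temp_z": temp_z, "effort_sd": eff_sd,
            "scales": scales}


def rescale_params(params: DMMParams, scales_from: dict, scales_to: dict) -> DMMParams:
    """Re-express coefficients under a different covariate standardization.

    Coefficients are defined relative to z-scores of the panel they were
    fit (or used to simulate) on. When a different panel — e.g. one with
    some circles filtered out — re-standardizes the raw covariates with
    its own means and sds, the *same* linear predictor corresponds to
    transformed coefficients:

        slope' = slope * sd_to / sd_from
        intercept' = intercept + sum_j slope_j * (mean_to_j - mean_from_j) / sd_from_j

    ``scales_from`` / ``scales_to`` are the ``"scales"`` dicts returned by
    :func:`covariate_design`.
    """
    def shift_block(vec, names):
        vec = np.asarray(vec, dtype=float).copy()
        b0 = vec[0]
        for j, name in enumerate(names, start=1):
            m_f, s_f = scales_from[name]
            m_t, s_t = scales_to[name]
            b0 += vec[j] * (m_t - m_f) / s_f
            vec[j] = vec[j] * s_t / s_f
        vec[0] = b0
        return vec

    det = shift_block([params.alpha0, params.a_e, params.a_m],
                      ("effort", "min_temp"))
    return DMMParams(
        beta_lambda=shift_block(params.beta_lambda, COVARIATE_NAMES),
        beta_omega=shift_block(params.beta_omega, COVARIATE_NAMES),
        beta_gamma=shift_block(params.beta_gamma, COVARIATE_NAMES),
        alpha0=float(det[0]),
        a_e=float(det[1]),
        a_m=float(det[2]),
    )


def linear_predictors(params: DMMParams, Z: np.ndarray,
                      effort_z: np.ndarray, temp_z: np.ndarray,
                      check: bool = True):
    """Invert the links: ``(Lambda_i1, omega_it, gamma_it, p_it)``.

    ``Z`` is the standardized (n, T, 5) covariate design; ``Lambda`` uses
    the covariates of the first year. Detection is strictly increasing in
    effort and decreasing in temperature by the sign constraints on
    ``a_e`` and ``a_m``.
    """
    if check:
        for j, name in enumerate(COVARIATE_NAMES, start=1):
            check_standardized(Z[:, :, j], name)
        check_standardized(effort_z, "effort")
        check_standardized(temp_z, "min_temp")
    lam = clip_rate(np.exp(Z[:, 0, :] @ params.beta_lambda))
    omega = clip_prob(expit(Z @ params.beta_omega))
    gamma = clip_rate(np.exp(Z @ params.beta_gamma))
    p = clip_prob(expit(params.alpha0 + params.a_e * effort_z + params.a_m * temp_z))
    return lam, omega, gamma, p


def poisson_logpmf(k: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Vectorized Poisson log-pmf; exact 0 at (k=0, mu=0); -inf for k < 0."""
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = xlogy(k, mu) - mu - gammaln(k + 1.0)
    return np.where(k < 0, -np.inf, out)


def binomial_logpmf(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorized Binomial log-pmf; -inf outside the support 0 <= k <= n."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    valid = (k >= 0) & (k <= n)
    ks = np.where(valid, k, 0.0)
    with np.errstate(invalid="ignore"):
        out = (gammaln(n + 1.0) - gammaln(ks + 1.0) - gammaln(n - ks + 1.0)
               + xlogy(ks, p) + xlog1py(n - ks, -p))
    return np.where(valid, out, -np.inf)


def complete_data_loglik(params: DMMParams, latent: LatentState,
                         panel: ObservationPanel,
                         design: dict | None = None) -> float:
    """Joint log density of latent states and observed counts.

    Sums, over circles and years, the initial-abundance Poisson term, the
    survival Binomial and recruitment Poisson transition terms, and the
    Binomial observation term at surveyed circle-years. A latent state
    outside the model support (e.g. ``S > N_prev`` or ``X > N``) yields
    ``-inf`` rather than an exception.
    """
    if design is None:
        design = covariate_design(panel)
    lam, omega, gamma, p = linear_predictors(
        params, design["Z"], design["effort_z"], design["temp_z"], check=False
    )
    N, S, R = latent.N, latent.S, latent.R
    ll = poisson_logpmf(N[:, 0], lam).sum()
    if N.shape[1] >= 2:
        Nprev = N[:, :-1]
        ll += binomial_logpmf(S[:, 1:], Nprev, omega[:, 1:]).sum()
        ll += poisson_logpmf(R[:, 1:], gamma[:, 1:] * Nprev).sum()
        if np.any(N[:, 1:] != S[:, 1:] + R[:, 1:]):
            return -np.inf
    obs = panel.observed
    if obs.any():
        ll += binomial_logpmf(panel.counts[obs], N[obs], p[obs]).sum()
    return float(ll)
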