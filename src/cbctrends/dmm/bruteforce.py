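"""Exact observed-data likelihood for tiny Dail-Madsen instances.

Marginalizes the complete-data likelihood over every latent configuration
(N, S, R) with abundances truncated at ``n_max``. Sites are independent,
and within a site the sum over paths factorizes over years, so the
exhaustive sum is evaluated by a forward recursion over N_t whose
transition kernel is itself an explicit sum over survivor counts:

    P(N_t = b | N_{t-1} = a) = sum_{s=0}^{min(a,b)} Bin(s; a, omega_t)
                                                  * Pois(b - s; gamma_t a)

This is the independent oracle against which the MCMC sampler is checked;
it shares no code path with the sampler beyond the link functions.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from ..types import DMMParams, ObservationPanel
from .likelihood import (
    binomial_logpmf,
    covariate_design,
    linear_predictors,
    poisson_logpmf,
)

DEFAULT_STATE_CAP = 50_000_000


def _transition_matrix(n_max: int, omega: float, gamma: float) -> np.ndarray:
    """Log transition kernel over N in {0..n_max}: entry [a, b] = log P(b | a)."""
    states = np.arange(n_max + 1)
    a = states[:, None, None]     # previous abundance
    b = states[None, :, None]     # next abundance
    s = states[None, None, :]     # survivors
    log_terms = (binomial_logpmf(s, a, omega)
                 + poisson_logpmf(b - s, gamma * a))
    # survivors beyond min(a, b) contribute -inf via the pmf supports
    return logsumexp(log_terms, axis=2)


def marginal_loglik_bruteforce(params: DMMParams, panel: ObservationPanel,
                               n_max: int = 30,
                               state_cap: int = DEFAULT_STATE_CAP) -> float:
    """Exact log observed-data likelihood with N truncated at ``n_max``.

    Only meant for tiny instances (a few sites and years). Refuses when the
    implied latent state space ``n_sites * n_years * (n_max+1)^2`` exceeds
    ``state_cap``, reporting the estimated size.
    """
    n, T = panel.n_circles, panel.n_years
    size = n * T * (n_max + 1) ** 2
    if size > state_cap:
        raise ValueError(
            f"latent state space too large for exhaustive marginalization: "
            f"~{size:.3g} transition terms exceeds the cap of {state_cap:.3g}"
        )
    design = covariate_design(panel)
    lam, omega, gamma, p = linear_predictors(
        params, design["Z"], design["effort_z"], design["temp_z"], check=False
    )
    states = np.arange(n_max + 1)
    obs = panel.observed
    total = 0.0
    for i in range(n):
        log_alpha = poisson_logpmf(states, lam[i])
        if obs[i, 0]:
            log_alpha = log_alpha + binomial_logpmf(panel.counts[i, 0], states, p[i, 0])
        for t in range(1, T):
            kernel = _transition_matrix(n_max, float(omega[i, t]), float(gamma[i, t]))
            log_alpha = logsumexp(log_alpha[:, None] + kernel, axis=0)
            if obs[i, t]:
                log_alpha = log_alpha + binomial_logpmf(panel.counts[i, t], states, p[i, t])
        total += float(logsumexp(log_alpha))
    return total


def grid_posterior(params: DMMParams, panel: ObservationPanel,
                   param_index: int, grid: np.ndarray,
                   prior_logpdf, n_max: int = 30) -> np.ndarray:
    """Normalized posterior over ``grid`` values of one coefficient.

    All other coefficients stay fixed at their values in ``params``;
    ``param_index`` addresses the 18-vector of
    :meth:`~cbctrends.types.DMMParams.to_vector`. Used as the exact
    reference distribution in sampler-validation tests.
    """
    base = params.to_vector()
    logpost = np.empty(grid.size)
    for j, g in enumerate(np.asarray(grid, dtype=float)):
        vec = base.copy()
        vec[param_index] = g
        theta = DMMParams.from_vector(vec)
        logpost[j] = (marginal_loglik_bruteforce(theta, panel, n_max=n_max)
                      + prior_logpdf(g))
    w = np.exp(logpost - logpost.max())
    return w / w.sum()
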