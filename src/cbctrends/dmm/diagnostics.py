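"""Convergence diagnostics and posterior abundance summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..types import AbundanceEstimate
from .sampler import PosteriorDraws


def gelman_rubin(draws, param_names=None) -> pd.Series:
    """Potential scale reduction factor (PSRF) per monitored parameter.

    Accepts a :class:`PosteriorDraws` or a raw array of shape
    ``(chains, iterations, parameters)``; only post-burn-in draws should be
    passed (PosteriorDraws already stores nothing else). Uses the classic
    between/within variance ratio

        R = sqrt( ((n-1)/n * W + B/n) / W )

    floored at 1.0: with finitely many draws the raw statistic dips
    slightly below 1 when chains agree (it is exactly sqrt((n-1)/n) for
    identical chains), and values below 1 carry no convergence information.
    Values above ~1.1 indicate the chains have not mixed.
    """
    if isinstance(draws, PosteriorDraws):
        if param_names is None:
            if draws.free_mask is not None and not draws.free_mask.all():
                param_names = [n for n, f in zip(draws.param_names, draws.free_mask) if f]
                arr = draws.params[:, :, draws.free_mask]
            else:
                param_names = draws.param_names
                arr = draws.params
        else:
            arr = draws.params
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, k = arr.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains; rerun with a multi-chain "
                         "configuration")
    if n < 10:
        raise ValueError(f"Gelman-Rubin needs >= 10 draws per chain, got {n}")
    chain_means = arr.mean(axis=1)                      # (m, k)
    chain_vars = arr.var(axis=1, ddof=1)                # (m, k)
    W = chain_vars.mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)          # B/n
    W_safe = np.where(W > 0, W, 1.0)
    var_hat = (n - 1) / n * W + B_over_n
    psrf = np.sqrt(var_hat / W_safe)
    psrf = np.where((W == 0) & (B_over_n == 0), 1.0, psrf)
    psrf = np.where((W == 0) & (B_over_n > 0), np.inf, psrf)
    psrf = np.maximum(psrf, 1.0)
    if param_names is None:
        param_names = [f"param[{i}]" for i in range(k)]
    return pd.Series(psrf, index=param_names, name="gelman_rubin")


def summarize_abundance(draws: PosteriorDraws) -> AbundanceEstimate:
    """Posterior mean, central 95% interval and ESS of N per circle-year.

    Interval endpoints are the empirical 2.5% and 97.5% quantiles of the
    pooled post-burn-in latent draws. The region-wide yearly series is the
    arithmetic mean of per-circle posterior means (circles enter equally,
    matching a mean-across-sites summary).
    """
    import arviz as az

    lat = draws.latent_N.astype(float)                  # (chains, draws, n, T)
    pooled = lat.reshape(-1, *lat.shape[2:])            # (chains*draws, n, T)
    mean = pooled.mean(axis=0)
    lo, hi = np.quantile(pooled, [0.025, 0.975], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ess = az.ess(az.convert_to_dataset(lat))["x"].to_numpy()

    n, T = mean.shape
    table = pd.DataFrame({
        "circle": np.repeat(draws.circles, T),
        "year": np.tile(draws.years, n),
        "mean": mean.ravel(),
        "lo95": lo.ravel(),
        "hi95": hi.ravel(),
        "ess": ess.ravel(),
    })
    yearly = pd.Series(mean.mean(axis=0), index=pd.Index(draws.years, name="year"),
                       name="mean_abundance")
    return AbundanceEstimate(table=table, yearly_mean=yearly)
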