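"""Metropolis-within-Gibbs sampler for the single-visit Dail-Madsen model.

The sampler alternates:

* scalar random-walk updates of the 18 regression coefficients under
  Normal(0, 10^2) priors, with the detection slopes constrained to
  half-lines (``a_e > 0``, ``a_m < 0``) by proposal rejection (equivalent
  to truncated-normal priors);
* latent-effort updates where the effort covariate was imputed: the true
  (standardized) effort is a latent variable with a normal measurement
  model centered at the imputed value, sd derived from the prediction
  interval width;
* integer random-walk updates of the latent states — initial abundance
  ``N[i,0]``, recruitment-driven abundance changes at each later year
  (changing ``R`` and hence ``N``), and survivor/recruit re-allocations at
  fixed ``N`` — vectorized across sites, with interior years updated on an
  odd/even checkerboard so that simultaneous proposals never share a
  likelihood term.

Every proposal respects (or is rejected by) the structural invariants
``N = S + R``, ``S <= N_prev`` and ``X <= N``. Proposal scales adapt
toward a 44% acceptance rate during burn-in and are frozen afterwards, so
the post-burn-in chain is a valid Markov chain. All randomness flows from
the user seed; chains use over-dispersed starts derived from seed offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, xlog1py, xlogy

from ..types import DMMParams, LatentState, ObservationPanel
from .likelihood import clip_prob, clip_rate, covariate_design

PRIOR_SD = 10.0
N_PARAMS = 18
_EFFORT_RULES = {"width": 1.0, "half": 0.5, "quarter": 0.25}


@dataclass
class MCMCConfig:
    """Iteration plan and numerical knobs of the sampler.

    ``effort_error_rule`` maps the stored prediction-interval width to the
    measurement-model sd: ``width`` (sd = full width), ``half`` (sd =
    width/2) or ``quarter`` (sd = width/4, i.e. the 2-SE half-width
    back-transformed to one SE; the default).
    """

    n_iter: int = 20_000
    burn_in: int = 10_000
    chains: int = 3
    thin: int = 1
    latent_thin: int = 20
    effort_error_rule: str = "quarter"
    adapt_interval: int = 100
    target_accept: float = 0.44
    overdispersion: float = 0.5   # sd of chain-start jitter on coefficients
    demographic_rounds: int = 0   # extra omega/gamma sweeps + S/R swaps per iteration
    detection_rounds: int = 1     # extra detection-block sweeps per iteration
    sr_gibbs_interval: int = 10   # iterations between exact S/R-split re-draws
    demog_marginal_interval: int = 1  # iterations between marginalized demog moves
    alpha_marginal_interval: int = 1  # iterations between marginalized ridge moves

    def __post_init__(self) -> None:
        if self.effort_error_rule not in _EFFORT_RULES:
            raise ValueError(f"effort_error_rule must be one of {sorted(_EFFORT_RULES)}")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")

    @classmethod
    def desk(cls, **kw) -> "MCMCConfig":
        """Desk-scale preset: 20,000 iterations, 10,000 burn-in, 3 chains."""
        return cls(**kw)

    @classmethod
    def production(cls, **kw) -> "MCMCConfig":
        """Production-scale preset: 100,000 iterations, 80,000 burn-in."""
        kw.setdefault("n_iter", 100_000)
        kw.setdefault("burn_in", 80_000)
        return cls(**kw)


@dataclass
class PosteriorDraws:
    """Post-burn-in draws plus the metadata needed to interpret them."""

    params: np.ndarray          # (chains, n_kept, 18)
    param_names: list
    latent_N: np.ndarray        # (chains, n_kept_latent, n, T) int32
    latent_S: np.ndarray
    latent_R: np.ndarray
    circles: np.ndarray
    years: np.ndarray
    config: MCMCConfig
    seed: int
    accept_rates: dict = field(default_factory=dict)
    free_mask: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    def to_dataframe(self):
        """Long table (chain, iteration, parameter, value) of coefficient draws."""
        import pandas as pd

        c, n, p = self.params.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), n * p),
            "iteration": np.tile(np.repeat(np.arange(n), p), c),
            "parameter": np.tile(self.param_names, c * n),
            "value": self.params.ravel(),
        })


def _prepare(panel: ObservationPanel, config: MCMCConfig) -> dict:
    panel.validate()
    obs = panel.observed
    if not obs.any():
        raise ValueError("panel has no observed counts at all; nothing to fit")
    keep = obs.any(axis=1)
    if not keep.all():
        raise ValueError(
            f"{int((~keep).sum())} circle(s) have no observed counts; apply the "
            "study filters before sampling"
        )
    design = covariate_design(panel)
    X = np.where(obs, np.nan_to_num(panel.counts), 0.0).astype(np.int64)
    width_z = panel.effort_width / design["effort_sd"]
    eff_mask = (width_z > 0) & obs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k_site = np.nanmean(np.where(obs, panel.counts, np.nan), axis=1)
    return {
        "X": X,
        "obs": obs,
        "Z": design["Z"],
        "effort_z": design["effort_z"],
        "temp_z": design["temp_z"],
        "eff_mask": eff_mask,
        "eff_prior_sd": width_z * _EFFORT_RULES[config.effort_error_rule],
        "n": panel.n_circles,
        "T": panel.n_years,
        "k_site": np.maximum(np.nan_to_num(k_site), 1.0),
    }


def _init_latent(X: np.ndarray, obs: np.ndarray) -> LatentState:
    n, T = X.shape
    m = np.where(obs, X, 0).max(axis=1)
    m = np.maximum(m + 1, 1)
    N = np.tile(m[:, None], (1, T)).astype(np.int64)
    S = np.zeros_like(N)
    R = np.zeros_like(N)
    if T >= 2:
        S[:, 1:] = (N[:, 1:] // 2)
        R[:, 1:] = N[:, 1:] - S[:, 1:]
    return LatentState(N=N, S=S, R=R)


def _init_theta(init: np.ndarray | None, rng: np.random.Generator,
                free: np.ndarray, jitter: float) -> np.ndarray:
    theta = np.zeros(N_PARAMS) if init is None else np.asarray(init, float).copy()
    theta[free] += rng.normal(0.0, jitter, int(free.sum()))
    if theta[16] <= 0:
        if init is not None and init[16] > 0:
            theta[16] = abs(theta[16])
        theta[16] = max(abs(theta[16]), 0.05)
    if theta[17] >= 0:
        theta[17] = -max(abs(theta[17]), 0.05)
    return theta


class _ChainState:
    """Mutable state of one chain; caches linear predictors and rates."""

    def __init__(self, data: dict, theta: np.ndarray, eff: np.ndarray,
                 latent: LatentState):
        self.data = data
        self.theta = theta
        self.eff = eff
        self.N, self.S, self.R = latent.N, latent.S, latent.R
        Z = data["Z"]
        self.eta_l = Z[:, 0, :] @ theta[0:5]
        self.eta_w = Z @ theta[5:10]
        self.eta_g = Z @ theta[10:15]
        self.refresh_p()
        self.refresh_rates()

    def refresh_p(self) -> None:
        t = self.theta
        self.eta_p = t[15] + t[16] * self.eff + t[17] * self.data["temp_z"]
        self.p = clip_prob(expit(self.eta_p))

    def refresh_rates(self) -> None:
        self.lam = clip_rate(np.exp(self.eta_l))
        self.omega = clip_prob(expit(self.eta_w))
        self.gamma = clip_rate(np.exp(self.eta_g))


def _loglik_lambda(eta_l, N0):
    lam = clip_rate(np.exp(eta_l))
    return (xlogy(N0, lam) - lam).sum()


def _loglik_omega(eta_w, S, Nprev):
    om = clip_prob(expit(eta_w))
    return (xlogy(S, om) + xlog1py(Nprev - S, -om)).sum()


def _loglik_gamma(eta_g, R, Nprev):
    gam = clip_rate(np.exp(eta_g))
    mu = gam * Nprev
    return (xlogy(R, mu) - mu).sum()


def _loglik_p(eta_p, X, N, obs):
    p = clip_prob(expit(eta_p))
    return (xlogy(X, p) + xlog1py(N - X, -p))[obs].sum()


def _update_params(st: _ChainState, rng, scales, free, accept, attempt) -> None:
    """One component-wise Metropolis sweep over the 18 coefficients.

    The current value of each block's log likelihood is computed once and
    updated on acceptance, so a proposal costs a single block evaluation.
    """
    d = st.data
    Z, X, obs = d["Z"], d["X"], d["obs"]
    N0 = st.N[:, 0]
    has_trans = st.N.shape[1] >= 2
    if has_trans:
        S1, R1, Nprev = st.S[:, 1:], st.R[:, 1:], st.N[:, :-1]
        cur_om = _loglik_omega(st.eta_w[:, 1:], S1, Nprev)
        cur_gm = _loglik_gamma(st.eta_g[:, 1:], R1, Nprev)
    cur_lam = _loglik_lambda(st.eta_l, N0)
    cur_p = _loglik_p(st.eta_p, X, st.N, obs)

    for j in range(N_PARAMS):
        if not free[j]:
            continue
        attempt[j] += 1
        step = scales[j] * rng.normal()
        new = st.theta[j] + step
        if (j == 16 and new <= 0) or (j == 17 and new >= 0):
            continue
        dprior = -(new ** 2 - st.theta[j] ** 2) / (2.0 * PRIOR_SD ** 2)
        if j < 5:
            eta_new = st.eta_l + step * Z[:, 0, j]
            prop = _loglik_lambda(eta_new, N0)
            dll = prop - cur_lam
        elif j < 10:
            if not has_trans:
                prop, dll = 0.0, 0.0
            else:
                eta_new = st.eta_w[:, 1:] + step * Z[:, 1:, j - 5]
                prop = _loglik_omega(eta_new, S1, Nprev)
                dll = prop - cur_om
        elif j < 15:
            if not has_trans:
                prop, dll = 0.0, 0.0
            else:
                eta_new = st.eta_g[:, 1:] + step * Z[:, 1:, j - 10]
                prop = _loglik_gamma(eta_new, R1, Nprev)
                dll = prop - cur_gm
        else:
            col = 1.0 if j == 15 else (st.eff if j == 16 else d["temp_z"])
            eta_new = st.eta_p + step * col
            prop = _loglik_p(eta_new, X, st.N, obs)
            dll = prop - cur_p
        if np.log(rng.random()) < dll + dprior:
            accept[j] += 1
            st.theta[j] = new
            if j < 5:
                st.eta_l = st.eta_l + step * Z[:, 0, j]
                cur_lam = prop
            elif j < 10:
                st.eta_w = st.eta_w + step * Z[:, :, j - 5]
                cur_om = prop
            elif j < 15:
                st.eta_g = st.eta_g + step * Z[:, :, j - 10]
                cur_gm = prop
            else:
                st.eta_p = eta_new
                st.p = clip_prob(expit(st.eta_p))
                cur_p = prop
    st.refresh_rates()


def _update_effort(st: _ChainState, rng, scale, counters) -> None:
    d = st.data
    mask = d["eff_mask"]
    if not mask.any():
        return
    mu = d["effort_z"][mask]
    sd = d["eff_prior_sd"][mask]
    cur = st.eff[mask]
    prop = cur + scale * rng.normal(size=cur.size)
    a_e = st.theta[16]
    eta_cur = st.eta_p[mask]
    eta_new = eta_cur + a_e * (prop - cur)
    X = d["X"][mask]
    N = st.N[mask]
    p_new = clip_prob(expit(eta_new))
    p_cur = clip_prob(expit(eta_cur))
    dll = (xlogy(X, p_new) + xlog1py(N - X, -p_new)
           - xlogy(X, p_cur) - xlog1py(N - X, -p_cur))
    dprior = -((prop - mu) ** 2 - (cur - mu) ** 2) / (2.0 * sd ** 2)
    acc = np.log(rng.random(cur.size)) < dll + dprior
    counters[0] += int(acc.sum())
    counters[1] += cur.size
    if acc.any():
        new_eff = st.eff[mask]
        new_eff[acc] = prop[acc]
        st.eff[mask] = new_eff
        new_eta = st.eta_p[mask]
        new_eta[acc] = eta_new[acc]
        st.eta_p[mask] = new_eta
        st.p = clip_prob(expit(st.eta_p))


class _BlockProposal:
    """Adaptive multivariate random-walk proposal for one coefficient block.

    Accumulates the running covariance of the block during burn-in
    (Welford updates) and proposes steps from N(0, s^2 * Sigma_hat), which
    traverses the correlated ridges that collinear covariates induce far
    faster than axis-aligned steps. The covariance and global scale are
    frozen at the end of burn-in, so retained draws come from a fixed
    Markov kernel.
    """

    def __init__(self, idx: np.ndarray):
        self.idx = idx
        d = idx.size
        self.mean = np.zeros(d)
        self.m2 = np.zeros((d, d))
        self.count = 0
        self.log_scale = np.log(2.38 / np.sqrt(d))
        self.chol = np.eye(d) * 0.05
        self.accept = 0
        self.attempt = 0

    def record(self, theta: np.ndarray) -> None:
        x = theta[self.idx]
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, x - self.mean)

    def refresh(self) -> None:
        if self.count > 200:
            cov = self.m2 / (self.count - 1)
            cov = cov + 1e-8 * np.eye(self.idx.size)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass
        if self.attempt > 0:
            rate = self.accept / self.attempt
            self.log_scale += np.clip(rate - 0.25, -0.3, 0.3)
            self.accept = 0
            self.attempt = 0

    def step(self, rng) -> np.ndarray:
        return np.exp(self.log_scale) * (self.chol @ rng.normal(size=self.idx.size))


def _update_block(st: _ChainState, rng, bp: _BlockProposal, kind: str) -> None:
    """Joint Metropolis update of one coefficient block (lambda/omega/gamma/alpha)."""
    d = st.data
    Z, X, obs = d["Z"], d["X"], d["obs"]
    has_trans = st.N.shape[1] >= 2
    step = bp.step(rng)
    bp.attempt += 1
    new = st.theta[bp.idx] + step
    if kind == "alpha":
        full = st.theta[15:18].copy()
        full[bp.idx - 15] = new
        if full[1] <= 0 or full[2] >= 0:
            return
    dprior = -((new ** 2).sum() - (st.theta[bp.idx] ** 2).sum()) / (2.0 * PRIOR_SD ** 2)
    if kind == "lambda":
        cols = Z[:, 0, bp.idx]
        eta_new = st.eta_l + cols @ step
        dll = _loglik_lambda(eta_new, st.N[:, 0]) - _loglik_lambda(st.eta_l, st.N[:, 0])
    elif kind == "demog":
        # joint survival + recruitment block: the two share near-collinear
        # anti-correlated ridges (growth-rate confounding), so they must
        # move together
        if not has_trans:
            return
        S1, R1, Nprev = st.S[:, 1:], st.R[:, 1:], st.N[:, :-1]
        om_sel = bp.idx < 10
        step_w, step_g = step[om_sel], step[~om_sel]
        eta_w_new = st.eta_w[:, 1:]
        eta_g_new = st.eta_g[:, 1:]
        if step_w.size:
            eta_w_new = eta_w_new + Z[:, 1:, bp.idx[om_sel] - 5] @ step_w
        if step_g.size:
            eta_g_new = eta_g_new + Z[:, 1:, bp.idx[~om_sel] - 10] @ step_g
        dll = (_loglik_omega(eta_w_new, S1, Nprev)
               - _loglik_omega(st.eta_w[:, 1:], S1, Nprev)
               + _loglik_gamma(eta_g_new, R1, Nprev)
               - _loglik_gamma(st.eta_g[:, 1:], R1, Nprev))
    else:
        cols = np.stack([np.ones_like(st.eff) if j == 15
                         else (st.eff if j == 16 else d["temp_z"])
                         for j in bp.idx], axis=-1)
        eta_new = st.eta_p + cols @ step
        dll = _loglik_p(eta_new, X, st.N, obs) - _loglik_p(st.eta_p, X, st.N, obs)
    if np.log(rng.random()) < dll + dprior:
        bp.accept += 1
        st.theta[bp.idx] = new
        if kind == "lambda":
            st.eta_l = eta_new
        elif kind == "demog":
            if step_w.size:
                st.eta_w = st.eta_w + Z[:, :, bp.idx[om_sel] - 5] @ step_w
            if step_g.size:
                st.eta_g = st.eta_g + Z[:, :, bp.idx[~om_sel] - 10] @ step_g
        else:
            st.eta_p = eta_new
            st.p = clip_prob(expit(st.eta_p))
        st.refresh_rates()


def _update_demographic_params(st: _ChainState, rng, scales, free,
                               accept, attempt) -> None:
    """Extra Metropolis sweep over the survival and recruitment coefficients.

    Survival and recruitment trade off against the latent S/R split, so
    these ten coefficients decorrelate more slowly than the rest;
    interleaving additional sweeps with S/R re-allocation moves speeds up
    that subspace without touching the other blocks.
    """
    d = st.data
    if st.N.shape[1] < 2:
        return
    Z = d["Z"]
    S1, R1, Nprev = st.S[:, 1:], st.R[:, 1:], st.N[:, :-1]
    cur_om = _loglik_omega(st.eta_w[:, 1:], S1, Nprev)
    cur_gm = _loglik_gamma(st.eta_g[:, 1:], R1, Nprev)
    for j in range(5, 15):
        if not free[j]:
            continue
        attempt[j] += 1
        step = scales[j] * rng.normal()
        new = st.theta[j] + step
        dprior = -(new ** 2 - st.theta[j] ** 2) / (2.0 * PRIOR_SD ** 2)
        if j < 10:
            eta_new = st.eta_w[:, 1:] + step * Z[:, 1:, j - 5]
            prop = _loglik_omega(eta_new, S1, Nprev)
            dll = prop - cur_om
        else:
            eta_new = st.eta_g[:, 1:] + step * Z[:, 1:, j - 10]
            prop = _loglik_gamma(eta_new, R1, Nprev)
            dll = prop - cur_gm
        if np.log(rng.random()) < dll + dprior:
            accept[j] += 1
            st.theta[j] = new
            if j < 10:
                st.eta_w = st.eta_w + step * Z[:, :, j - 5]
                cur_om = prop
            else:
                st.eta_g = st.eta_g + step * Z[:, :, j - 10]
                cur_gm = prop
    st.refresh_rates()


def _update_detection_params(st: _ChainState, rng, scales, free,
                             accept, attempt) -> None:
    """Extra Metropolis sweep over the detection block (alpha0, a_e, a_m).

    The detection intercept rides a ridge against total abundance; paired
    with whole-trajectory shift moves this sweep speeds its mixing.
    """
    d = st.data
    X, obs = d["X"], d["obs"]
    cur_p = _loglik_p(st.eta_p, X, st.N, obs)
    for j in (15, 16, 17):
        if not free[j]:
            continue
        attempt[j] += 1
        step = scales[j] * rng.normal()
        new = st.theta[j] + step
        if (j == 16 and new <= 0) or (j == 17 and new >= 0):
            continue
        dprior = -(new ** 2 - st.theta[j] ** 2) / (2.0 * PRIOR_SD ** 2)
        col = 1.0 if j == 15 else (st.eff if j == 16 else d["temp_z"])
        eta_new = st.eta_p + step * col
        prop = _loglik_p(eta_new, X, st.N, obs)
        if np.log(rng.random()) < prop - cur_p + dprior:
            accept[j] += 1
            st.theta[j] = new
            st.eta_p = eta_new
            st.p = clip_prob(expit(st.eta_p))
            cur_p = prop


def _propose_delta(rng, shape):
    """Symmetric two-scale integer steps: small moves mix fine-grained
    detail, occasional large moves traverse high-abundance states."""
    mag_small = rng.integers(1, 4, size=shape)
    mag_large = rng.integers(1, 16, size=shape)
    mag = np.where(rng.random(shape) < 0.7, mag_small, mag_large)
    sign = rng.integers(0, 2, size=shape) * 2 - 1
    return sign * mag


def _gammaln1(x):
    return gammaln(x + 1.0)


def _binom_n_delta(k, n_new, n_old, log1m_p):
    """log Bin(k; n_new, p) - log Bin(k; n_old, p), valid supports assumed."""
    return (_gammaln1(n_new) - _gammaln1(n_new - k)
            - _gammaln1(n_old) + _gammaln1(n_old - k)
            + (n_new - n_old) * log1m_p)


class _Precomp:
    """Per-iteration caches of slowly-changing transforms of the rates."""

    def __init__(self, st: _ChainState):
        self.log1m_p = np.log1p(-st.p)
        self.log1m_om = np.log1p(-st.omega)
        self.log_lam = np.log(st.lam)


def _update_N0(st: _ChainState, rng, counters, pc: _Precomp) -> None:
    d = st.data
    n, T = d["n"], d["T"]
    X0, obs0 = d["X"][:, 0], d["obs"][:, 0]
    N0 = st.N[:, 0]
    delta = _propose_delta(rng, n)
    N0p = N0 + delta
    valid = N0p >= 0
    valid &= ~obs0 | (X0 <= N0p)
    if T >= 2:
        valid &= st.S[:, 1] <= N0p
    N0s = np.where(valid, N0p, N0)
    dll = (N0s - N0) * pc.log_lam - _gammaln1(N0s) + _gammaln1(N0)
    if obs0.any():
        dobs = _binom_n_delta(X0, N0s, N0, pc.log1m_p[:, 0])
        dll = dll + np.where(obs0, dobs, 0.0)
    if T >= 2:
        S1, R1 = st.S[:, 1], st.R[:, 1]
        gm1 = st.gamma[:, 1]
        dll = dll + _binom_n_delta(S1, N0s, N0, pc.log1m_om[:, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            dll = dll + xlogy(R1, N0s) - xlogy(R1, N0) - gm1 * (N0s - N0)
    dll = np.where(valid, dll, -np.inf)
    acc = np.log(rng.random(n)) < dll
    counters[0] += int(acc.sum())
    counters[1] += n
    st.N[acc, 0] = N0p[acc]


def _update_R_batch(st: _ChainState, rng, ts: np.ndarray, counters,
                    pc: _Precomp) -> None:
    """Joint R/N random walk at the year indices ``ts`` (all >= 1, stride 2)."""
    if ts.size == 0:
        return
    d = st.data
    n, T = d["n"], d["T"]
    X, obs = d["X"][:, ts], d["obs"][:, ts]
    N = st.N[:, ts]
    R = st.R[:, ts]
    Nprev = st.N[:, ts - 1]
    delta = _propose_delta(rng, (n, ts.size))
    Rp, Np = R + delta, N + delta
    valid = (Rp >= 0) & (Np >= 0)
    valid &= ~obs | (X <= Np)
    has_next = ts + 1 <= T - 1
    if has_next.any():
        nxt = ts[has_next] + 1
        valid[:, has_next] &= st.S[:, nxt] <= Np[:, has_next]
    Rp_s = np.where(valid, Rp, R)
    Np_s = np.where(valid, Np, N)
    gam = st.gamma[:, ts]
    with np.errstate(divide="ignore", invalid="ignore"):
        logmu = np.log(gam * Nprev)
    dll = ((Rp_s - R) * np.where(Nprev > 0, logmu, 0.0)
           - _gammaln1(Rp_s) + _gammaln1(R))
    dll = np.where((Nprev == 0) & (Rp_s > 0), -np.inf, dll)
    dobs = _binom_n_delta(X, Np_s, N, pc.log1m_p[:, ts])
    dll = dll + np.where(obs, dobs, 0.0)
    if has_next.any():
        nxt = ts[has_next] + 1
        Snext, Rnext = st.S[:, nxt], st.R[:, nxt]
        gm_n = st.gamma[:, nxt]
        sub = has_next
        Nn, Nps = N[:, sub], Np_s[:, sub]
        dtr = _binom_n_delta(Snext, Nps, Nn, pc.log1m_om[:, nxt])
        with np.errstate(divide="ignore", invalid="ignore"):
            dtr = dtr + xlogy(Rnext, Nps) - xlogy(Rnext, Nn) - gm_n * (Nps - Nn)
        add = np.zeros_like(dll)
        add[:, sub] = dtr
        dll = dll + add
    dll = np.where(valid, dll, -np.inf)
    acc = np.log(rng.random(dll.shape)) < dll
    counters[0] += int(acc.sum())
    counters[1] += acc.size
    if acc.any():
        Rcol = st.R[:, ts]
        Ncol = st.N[:, ts]
        Rcol[acc] = Rp[acc]
        Ncol[acc] = Np[acc]
        st.R[:, ts] = Rcol
        st.N[:, ts] = Ncol


def _update_SR_swap(st: _ChainState, rng, counters, pc: _Precomp) -> None:
    """Shift units between survivors and recruits at fixed N, all years at once."""
    d = st.data
    T = d["T"]
    if T < 2:
        return
    S, R = st.S[:, 1:], st.R[:, 1:]
    Nprev = st.N[:, :-1]
    gam = st.gamma[:, 1:]
    logit_om = st.eta_w[:, 1:]
    delta = _propose_delta(rng, S.shape)
    Sp, Rp = S + delta, R - delta
    valid = (Sp >= 0) & (Rp >= 0) & (Sp <= Nprev)
    Sp_s = np.where(valid, Sp, S)
    Rp_s = np.where(valid, Rp, R)
    with np.errstate(divide="ignore", invalid="ignore"):
        logmu = np.log(gam * Nprev)
    dll = ((Sp_s - S) * logit_om
           - _gammaln1(Sp_s) - _gammaln1(Nprev - Sp_s)
           + _gammaln1(S) + _gammaln1(Nprev - S)
           + (Rp_s - R) * np.where(Nprev > 0, logmu, 0.0)
           - _gammaln1(Rp_s) + _gammaln1(R))
    dll = np.where(valid & ~((Nprev == 0) & (Rp_s > 0)), dll, -np.inf)
    acc = np.log(rng.random(dll.shape)) < dll
    counters[0] += int(acc.sum())
    counters[1] += acc.size
    if acc.any():
        S[acc] = Sp[acc]
        R[acc] = Rp[acc]
        st.S[:, 1:] = S
        st.R[:, 1:] = R


def _update_shift(st: _ChainState, rng, counters, pc: _Precomp) -> None:
    """Shift a site's whole latent trajectory by an integer delta.

    N[i, t] -> N[i, t] + d for every t (recruits absorb the change:
    R[i, t] -> R[i, t] + d, survivors unchanged). Single-year random walks
    decorrelate slowly when detection and abundance trade off; this move
    lets the total-abundance scale of a site mix against the detection and
    initial-abundance intercepts.
    """
    d = st.data
    n, T = d["n"], d["T"]
    X, obs = d["X"], d["obs"]
    delta = _propose_delta(rng, n)
    N0 = st.N[:, 0]
    Np0 = N0 + delta
    valid = Np0 >= 0
    if T >= 2:
        valid &= (st.R[:, 1:] + delta[:, None] >= 0).all(axis=1)
        valid &= (st.S[:, 1:] <= st.N[:, :-1] + delta[:, None]).all(axis=1)
    Nnew = st.N + delta[:, None]
    valid &= (~obs | (X <= Nnew)).all(axis=1)
    dsafe = np.where(valid, delta, 0)
    N0s = N0 + dsafe
    dll = dsafe * pc.log_lam - _gammaln1(N0s) + _gammaln1(N0)
    Nnew_s = st.N + dsafe[:, None]
    dobs = _binom_n_delta(X, Nnew_s, st.N, pc.log1m_p)
    dll = dll + np.where(obs, dobs, 0.0).sum(axis=1)
    if T >= 2:
        S1, R1 = st.S[:, 1:], st.R[:, 1:]
        Nprev = st.N[:, :-1]
        Nprev_new = Nnew_s[:, :-1]
        gm = st.gamma[:, 1:]
        R1_new = R1 + dsafe[:, None]
        dtr = _binom_n_delta(S1, Nprev_new, Nprev, pc.log1m_om[:, 1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            dtr = (dtr + xlogy(R1_new, Nprev_new) - xlogy(R1, Nprev)
                   + dsafe[:, None] * np.log(gm) - gm * dsafe[:, None]
                   - _gammaln1(R1_new) + _gammaln1(R1))
        dtr = np.where((Nprev_new == 0) & (R1_new > 0), -np.inf, dtr)
        dll = dll + dtr.sum(axis=1)
    dll = np.where(valid, dll, -np.inf)
    acc = np.log(rng.random(n)) < dll
    counters[0] += int(acc.sum())
    counters[1] += n
    if acc.any():
        st.N[acc] += delta[acc, None]
        if T >= 2:
            st.R[acc, 1:] += delta[acc, None]


def _get_gammaln1_table(data: dict, needed: int) -> np.ndarray:
    """Cached gammaln(k+1) lookups for integer k up to at least ``needed``."""
    tab = data.get("_gammaln1_table")
    if tab is None or tab.size <= needed:
        data["_gammaln1_table"] = gammaln(np.arange(max(needed + 1, 256) * 2,
                                                    dtype=float) + 1.0)
    return data["_gammaln1_table"]


def _gibbs_SR(st: _ChainState, rng) -> None:
    """Exact Gibbs re-draw of the survivor/recruit split given the N path.

    Conditional on N[i,t-1], N[i,t] and the rates, the survivor count has
    the discrete density  p(s) ~ Bin(s; N_prev, omega) * Pois(N_t - s;
    gamma * N_prev)  on  0 <= s <= min(N_prev, N_t); it is drawn exactly
    (inverse CDF on a windowed log-concave weight vector). Re-drawing the
    split removes the random-walk stickiness that otherwise throttles
    mixing of the survival and recruitment coefficients.
    """
    if st.data["T"] < 2:
        return
    from . import _kernels

    tab = _get_gammaln1_table(st.data, int(st.N.max()) + 1)
    u = rng.random(st.N[:, 1:].shape)
    with np.errstate(divide="ignore"):
        log_gamma = np.log(st.gamma[:, 1:])
    Snew = _kernels.sample_sr(st.N[:, :-1], st.N[:, 1:], st.eta_w[:, 1:],
                              log_gamma, tab, u)
    st.S[:, 1:] = Snew
    st.R[:, 1:] = st.N[:, 1:] - Snew


def _trans_marginal(st: _ChainState, N: np.ndarray, eta_w1: np.ndarray,
                    gamma1: np.ndarray) -> float:
    """Survivor-marginalized transition log likelihood of an N path:
    sum over sites and transitions of log sum_s Bin(s; N_prev, omega) *
    Pois(N_t - s; gamma * N_prev)."""
    from . import _kernels

    tab = _get_gammaln1_table(st.data, int(N.max()) + 1)
    with np.errstate(divide="ignore"):
        lg = np.log(gamma1)
    return float(_kernels.trans_marginal_loglik(N[:, :-1], N[:, 1:],
                                                eta_w1, lg, tab))


def _update_demog_marginal(st: _ChainState, rng, bp: _BlockProposal) -> bool:
    """Joint survival/recruitment block move with the S/R split marginalized.

    The proposal is accepted using the survivor-marginalized transition
    likelihood P(N | theta), so the acceptance ratio does not involve the
    current S/R split at all; on acceptance the split is re-drawn from its
    exact conditional under the new coefficients. This is what finally
    decorrelates the demographic coefficients from the latent split —
    without it they random-walk along a stiff ridge.
    """
    d = st.data
    if d["T"] < 2:
        return False
    Z = d["Z"]
    step = bp.step(rng)
    bp.attempt += 1
    new = st.theta[bp.idx] + step
    dprior = -((new ** 2).sum() - (st.theta[bp.idx] ** 2).sum()) / (2.0 * PRIOR_SD ** 2)
    om_sel = bp.idx < 10
    step_w, step_g = step[om_sel], step[~om_sel]
    eta_w_new = st.eta_w[:, 1:]
    eta_g_new = st.eta_g[:, 1:]
    if step_w.size:
        eta_w_new = eta_w_new + Z[:, 1:, bp.idx[om_sel] - 5] @ step_w
    if step_g.size:
        eta_g_new = eta_g_new + Z[:, 1:, bp.idx[~om_sel] - 10] @ step_g
    gamma_new = clip_rate(np.exp(eta_g_new))

    cur = _trans_marginal(st, st.N, st.eta_w[:, 1:], st.gamma[:, 1:])
    prop = _trans_marginal(st, st.N, eta_w_new, gamma_new)
    if np.log(rng.random()) < prop - cur + dprior:
        bp.accept += 1
        st.theta[bp.idx] = new
        if step_w.size:
            st.eta_w = st.eta_w + Z[:, :, bp.idx[om_sel] - 5] @ step_w
        if step_g.size:
            st.eta_g = st.eta_g + Z[:, :, bp.idx[~om_sel] - 10] @ step_g
        st.refresh_rates()
        _gibbs_SR(st, rng)
        return True
    return False


def _update_alpha_scale_marginal(st: _ChainState, rng, scale_u: float,
                                 k_site: np.ndarray, counters,
                                 free_alpha0: bool) -> None:
    """Detection-abundance ridge move with the S/R split marginalized.

    ``alpha0 + u`` is proposed paired with
    opposite-signed whole-trajectory shifts — but accepted through the
    survivor-marginalized transition likelihood P(N | theta), so the move
    is not penalized for the recruit-count mismatch a raw shift creates;
    the split is re-drawn exactly on acceptance. This is what lets the
    detection intercept traverse its ridge at full stride.
    """
    if not free_alpha0:
        return
    d = st.data
    n, T = d["n"], d["T"]
    X, obs = d["X"], d["obs"]
    u = scale_u * rng.normal()
    m = rng.poisson(np.abs(u) * k_site)
    delta = (-int(np.sign(u))) * m
    counters[1] += 1

    Nnew = st.N + delta[:, None]
    if Nnew.min() < 0 or np.any(obs & (X > Nnew)):
        return

    eta_p_new = st.eta_p + u
    dll = _loglik_p(eta_p_new, X, Nnew, obs) - _loglik_p(st.eta_p, X, st.N, obs)
    dll += (_gammaln1(Nnew) - _gammaln1(Nnew - X)
            - _gammaln1(st.N) + _gammaln1(st.N - X))[obs].sum()
    N0, Np0 = st.N[:, 0], Nnew[:, 0]
    dll += float((delta * np.log(st.lam) - _gammaln1(Np0) + _gammaln1(N0)).sum())
    if T >= 2:
        cur = _trans_marginal(st, st.N, st.eta_w[:, 1:], st.gamma[:, 1:])
        prop = _trans_marginal(st, Nnew, st.eta_w[:, 1:], st.gamma[:, 1:])
        dll += prop - cur
    a0 = st.theta[15]
    dll += -((a0 + u) ** 2 - a0 ** 2) / (2.0 * PRIOR_SD ** 2)
    if np.log(rng.random()) < dll:
        counters[0] += 1
        st.theta[15] = a0 + u
        st.eta_p = eta_p_new
        st.p = clip_prob(expit(st.eta_p))
        st.N = Nnew
        if T >= 2:
            _gibbs_SR(st, rng)


def _run_chain(data: dict, config: MCMCConfig, seed_seq, init: np.ndarray | None,
               free: np.ndarray, chain_id: int):
    rng = np.random.default_rng(seed_seq)
    theta = _init_theta(init, rng, free, config.overdispersion if chain_id else 0.0)
    if not free[16]:
        theta[16] = init[16]
    if not free[17]:
        theta[17] = init[17]
    latent = _init_latent(data["X"], data["obs"])
    st = _ChainState(data, theta, data["effort_z"].copy(), latent)

    T = data["T"]
    ts_odd = np.arange(1, T, 2)
    ts_even = np.arange(2, T, 2)

    scales = np.full(N_PARAMS, 0.1)
    eff_scale = 0.5
    p_accept = np.zeros(N_PARAMS)
    p_attempt = np.zeros(N_PARAMS)
    eff_ctr = [0, 0]
    lat_ctr = [0, 0]
    am_scale = 0.1
    am_ctr = [0, 0]

    blocks = []
    for kind, span in (("lambda", range(0, 5)), ("demog", range(5, 15)),
                       ("alpha", range(15, 18))):
        idx = np.array([j for j in span if free[j]], dtype=int)
        if idx.size:
            blocks.append((kind, _BlockProposal(idx)))
    demog_idx = np.array([j for j in range(5, 15) if free[j]], dtype=int)
    bp_marg = _BlockProposal(demog_idx) if demog_idx.size else None

    n_kept = (config.n_iter - config.burn_in) // config.thin
    kept_params = np.empty((n_kept, N_PARAMS))
    n_kept_latent = (config.n_iter - config.burn_in) // config.latent_thin
    kN = np.empty((n_kept_latent, data["n"], T), dtype=np.int32)
    kS = np.empty_like(kN)
    kR = np.empty_like(kN)
    ki = kl = 0

    for it in range(config.n_iter):
        _update_effort(st, rng, eff_scale, eff_ctr)
        _update_params(st, rng, scales, free, p_accept, p_attempt)
        for kind, bp in blocks:
            _update_block(st, rng, bp, kind)
        for _ in range(config.demographic_rounds):
            _update_SR_swap(st, rng, lat_ctr, None)
            _update_demographic_params(st, rng, scales, free, p_accept, p_attempt)
            for kind, bp in blocks:
                if kind == "demog":
                    _update_block(st, rng, bp, kind)
        pc = _Precomp(st)
        _update_N0(st, rng, lat_ctr, pc)
        _update_R_batch(st, rng, ts_odd, lat_ctr, pc)
        _update_R_batch(st, rng, ts_even, lat_ctr, pc)
        _update_SR_swap(st, rng, lat_ctr, pc)
        _update_shift(st, rng, lat_ctr, pc)
        for _ in range(config.detection_rounds):
            _update_detection_params(st, rng, scales, free, p_accept, p_attempt)
        if bp_marg is not None and (it + 1) % config.demog_marginal_interval == 0:
            _update_demog_marginal(st, rng, bp_marg)
        if (it + 1) % config.alpha_marginal_interval == 0:
            _update_alpha_scale_marginal(st, rng, am_scale, data["k_site"],
                                         am_ctr, bool(free[15]))
        if (it + 1) % config.sr_gibbs_interval == 0:
            _gibbs_SR(st, rng)

        adapting = it < config.burn_in
        if adapting:
            for _, bp in blocks:
                bp.record(st.theta)
            if bp_marg is not None:
                bp_marg.record(st.theta)
            if (it + 1) % config.adapt_interval == 0:
                for _, bp in blocks:
                    bp.refresh()
                if bp_marg is not None:
                    bp_marg.refresh()
        if adapting and (it + 1) % config.adapt_interval == 0:
            with np.errstate(invalid="ignore"):
                rates = np.where(p_attempt > 0, p_accept / np.maximum(p_attempt, 1), 0.0)
            scales *= np.exp(np.clip(rates - config.target_accept, -0.5, 0.5))
            scales = np.clip(scales, 1e-4, 10.0)
            if eff_ctr[1] > 0:
                eff_scale *= np.exp(np.clip(eff_ctr[0] / eff_ctr[1]
                                            - config.target_accept, -0.5, 0.5))
                eff_scale = float(np.clip(eff_scale, 1e-3, 5.0))
            if am_ctr[1] > 0:
                am_scale *= np.exp(np.clip(am_ctr[0] / am_ctr[1] - 0.25,
                                           -0.5, 0.5))
                am_scale = float(np.clip(am_scale, 1e-3, 2.0))
                am_ctr[0] = am_ctr[1] = 0
            p_accept[:] = 0
            p_attempt[:] = 0
            eff_ctr[0] = eff_ctr[1] = 0

        if it >= config.burn_in:
            k = it - config.burn_in
            if k % config.thin == 0 and ki < n_kept:
                kept_params[ki] = st.theta
                ki += 1
            if k % config.latent_thin == 0 and kl < n_kept_latent:
                kN[kl] = st.N
                kS[kl] = st.S
                kR[kl] = st.R
                kl += 1

    rates = {
        "params": float(np.mean(np.where(p_attempt > 0,
                                         p_accept / np.maximum(p_attempt, 1), np.nan))),
        "latent": lat_ctr[0] / max(lat_ctr[1], 1),
    }
    return kept_params[:ki], kN[:kl], kS[:kl], kR[:kl], rates


def sample_posterior(panel: ObservationPanel, config: MCMCConfig | None = None,
                     seed: int = 0, init_params: DMMParams | None = None,
                     free_params: np.ndarray | list | None = None) -> PosteriorDraws:
    """Draw from the joint posterior over coefficients and latent abundances.

    Parameters
    ----------
    panel
        Assembled observation panel (filtered; effort complete, with
        interval widths where imputed).
    config
        Iteration plan; :meth:`MCMCConfig.desk` by default.
    seed
        Master seed; chain c uses the spawned stream ``(seed, c)``.
    init_params
        Starting coefficients (sign constraints auto-corrected with a
        warning); zeros by default.
    free_params
        Optional boolean mask (length 18, ordering of
        :meth:`DMMParams.param_names`) selecting which coefficients are
        sampled; the rest stay fixed at their initial values. Used by the
        oracle-validation tests that profile a single coefficient.
    """
    config = config or MCMCConfig()
    if config.chains < 1:
        raise ValueError("need at least one chain")
    data = _prepare(panel, config)

    init = None
    if init_params is not None:
        init = init_params.to_vector().copy()
    free = np.ones(N_PARAMS, dtype=bool)
    if free_params is not None:
        free = np.asarray(free_params, dtype=bool)
        if free.shape != (N_PARAMS,):
            raise ValueError(f"free_params must have length {N_PARAMS}")
        if init is None:
            init = np.zeros(N_PARAMS)
            init[16], init[17] = 0.5, -0.5
            warnings.warn("fixing parameters without init_params: fixed values "
                          "default to 0 (a_e=0.5, a_m=-0.5)")

    chains_p, chains_N, chains_S, chains_R, rates = [], [], [], [], []
    for c in range(config.chains):
        ss = np.random.SeedSequence([int(seed), c])
        kp, kN, kS, kR, r = _run_chain(data, config, ss, init, free, c)
        chains_p.append(kp)
        chains_N.append(kN)
        chains_S.append(kS)
        chains_R.append(kR)
        rates.append(r)

    return PosteriorDraws(
        params=np.stack(chains_p),
        param_names=DMMParams.param_names(),
        latent_N=np.stack(chains_N),
        latent_S=np.stack(chains_S),
        latent_R=np.stack(chains_R),
        circles=panel.circles,
        years=panel.years,
        config=config,
        seed=int(seed),
        accept_rates={"chains": rates},
        free_mask=free,
    )
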