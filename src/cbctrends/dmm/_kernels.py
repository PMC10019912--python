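"""Numba kernels for the survivor-split marginalization and Gibbs sampling.

Both kernels work cell-by-cell on the transition grid. For each transition
(N_prev = a -> N_t = b) the survivor count s has log weight

    w(s) = -lgamma(s+1) - lgamma(a-s+1) - lgamma(b-s+1) + s * coef,
    coef = logit(omega) - log(gamma * a),

on the support 0 <= s <= min(a, b); w is log-concave, so its mode is found
exactly by binary search on the monotone ratio w(s+1) - w(s), and a window
of ~10 standard deviations around the mode carries all numerically
relevant mass. Scalar loops avoid the large temporary arrays a vectorized
implementation needs, which matters because these kernels run inside the
MCMC iteration loop.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=False)
def _cell_window(a, b, ew, lg):
    """Mode and half-width of the survivor-weight window for one transition."""
    smax = a if a < b else b
    # omega and gamma * a on the natural scale
    om = 1.0 / (1.0 + np.exp(-ew))
    mu = np.exp(lg) * a
    coef = ew - np.log(mu)
    # binary search for the largest s with w(s+1) >= w(s)
    lo, hi = 0, smax
    while lo < hi:
        mid = (lo + hi) // 2
        # w(mid+1) - w(mid) = log((a-mid)(b-mid)) - log(mid+1) + coef
        up = (np.log((a - mid) * (b - mid) + 1e-300) - np.log(mid + 1.0) + coef)
        if up > 0.0:
            lo = mid + 1
        else:
            hi = mid
    mode = lo
    var_bin = a * om * (1.0 - om)
    var_poi = mu
    v = var_bin if var_bin < var_poi else var_poi
    denom = 1.0 / (var_bin + 1e-12) + 1.0 / (var_poi + 1e-12)
    v = 1.0 / denom
    half = 8 + int(3.5 * np.sqrt(v + 1.0))
    w_lo = mode - half
    w_hi = mode + half
    if w_lo < 0:
        w_lo = 0
    if w_hi > smax:
        w_hi = smax
    return w_lo, w_hi, coef, mode


@nb.njit(cache=False)
def _extend_window(w_lo, w_hi, smax, coef, a, b, tab, m):
    """Grow the window until its edge weights are negligible (< m - 36).

    The local-curvature width can undershoot when the weight profile is
    nearly flat (near-critical transitions), so the bounds are pushed out
    adaptively; log-concavity guarantees the edges only decay further.
    """
    step = (w_hi - w_lo) // 2 + 8
    while w_lo > 0:
        w = -tab[w_lo] - tab[a - w_lo] - tab[b - w_lo] + w_lo * coef
        if w < m - 30.0:
            break
        w_lo = w_lo - step if w_lo - step > 0 else 0
    while w_hi < smax:
        w = -tab[w_hi] - tab[a - w_hi] - tab[b - w_hi] + w_hi * coef
        if w < m - 30.0:
            break
        w_hi = w_hi + step if w_hi + step < smax else smax
    return w_lo, w_hi


@nb.njit(cache=False)
def trans_marginal_loglik(Nprev, Nt, eta_w, log_gamma, tab):
    """Sum over transitions of log P(N_t | N_prev) with survivors summed out."""
    n, T1 = Nprev.shape
    total = 0.0
    for i in range(n):
        for t in range(T1):
            a = Nprev[i, t]
            b = Nt[i, t]
            if a == 0:
                if b > 0:
                    return -np.inf
                continue
            ew = eta_w[i, t]
            lg = log_gamma[i, t]
            w_lo, w_hi, coef, mode = _cell_window(a, b, ew, lg)
            smax = a if a < b else b
            m = -tab[mode] - tab[a - mode] - tab[b - mode] + mode * coef
            w_lo, w_hi = _extend_window(w_lo, w_hi, smax, coef, a, b, tab, m)
            acc = 0.0
            for s in range(w_lo, w_hi + 1):
                w = -tab[s] - tab[a - s] - tab[b - s] + s * coef
                acc += np.exp(w - m)
            # s-independent parts: log C(a, .) normalizer and Poisson constant
            if ew > 0.0:
                l1m = -ew - np.log1p(np.exp(-ew))
            else:
                l1m = -np.log1p(np.exp(ew))
            lmu = lg + np.log(a)
            total += (tab[a] + a * l1m + b * lmu - np.exp(lmu)
                      + m + np.log(acc))
    return total


@nb.njit(cache=False)
def sample_sr(Nprev, Nt, eta_w, log_gamma, tab, u):
    """Inverse-CDF draw of the survivor count for every transition.

    ``u`` holds one uniform variate per transition; returns the sampled
    survivor matrix.
    """
    n, T1 = Nprev.shape
    out = np.zeros((n, T1), dtype=np.int64)
    for i in range(n):
        for t in range(T1):
            a = Nprev[i, t]
            b = Nt[i, t]
            if a == 0 or b == 0:
                out[i, t] = 0
                continue
            ew = eta_w[i, t]
            lg = log_gamma[i, t]
            w_lo, w_hi, coef, mode = _cell_window(a, b, ew, lg)
            smax = a if a < b else b
            m = -tab[mode] - tab[a - mode] - tab[b - mode] + mode * coef
            w_lo, w_hi = _extend_window(w_lo, w_hi, smax, coef, a, b, tab, m)
            acc = 0.0
            for s in range(w_lo, w_hi + 1):
                acc += np.exp(-tab[s] - tab[a - s] - tab[b - s] + s * coef - m)
            target = u[i, t] * acc
            run = 0.0
            pick = w_hi
            for s in range(w_lo, w_hi + 1):
                run += np.exp(-tab[s] - tab[a - s] - tab[b - s] + s * coef - m)
                if run >= target:
                    pick = s
                    break
            out[i, t] = pick
    return out
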