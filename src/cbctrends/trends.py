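"""Abundance trajectories: GAM smoothing, 3-year derivatives, run classification.

Posterior mean abundances are noisy year to year; a generalized additive
model (penalized cubic regression spline of abundance on year, penalty
chosen by GCV) dampens short-interval jumps before rates of change are
measured. The rate of change is summarized by first differences of the
fitted curve over consecutive non-overlapping 3-year windows anchored at
the start of the detection-trimmed series; maximal same-sign runs of these
derivative steps classify a trajectory as temporally non-stationary (a
sustained increasing *and* a sustained decreasing period of at least five
years each), as showing a >= 15-year decline, or a >= 8-year increase.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import AbundanceEstimate, InsufficientDataError, RunClassification, TrendCurve

MIN_SERIES_LENGTH = 8
STEP_YEARS = 3
ZERO_TOL = 1e-12


def mean_abundance_series(estimates: AbundanceEstimate,
                          detection_years) -> pd.Series:
    """Region-wide yearly mean abundance, trimmed to the detection range.

    ``detection_years`` lists years in which the species was actually
    detected; estimates outside ``[min, max]`` of that list are removed so
    the trend never extrapolates beyond the window in which the species
    was recorded.
    """
    detection_years = np.asarray(list(detection_years), dtype=int)
    if detection_years.size == 0:
        raise ValueError("species has no detection years; cannot build a trend")
    lo, hi = detection_years.min(), detection_years.max()
    series = estimates.yearly_mean
    return series[(series.index >= lo) & (series.index <= hi)]


def _fit_cubic_gam(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Penalized cubic B-spline fit with GCV-selected penalty weight."""
    from statsmodels.gam.api import BSplines, GLMGam

    df = int(np.clip(len(y) // 4, 4, 10))
    bs = BSplines(x[:, None], df=[df], degree=[3], include_intercept=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GLMGam(y, smoother=bs)
        model.fit()                       # select_penweight needs a fitted scale
        alpha = model.select_penweight(method="minimize")[0]
        res = GLMGam(y, smoother=bs, alpha=alpha).fit()
    return np.asarray(res.fittedvalues)


def _fit_thin_plate(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smoothing-spline fallback (the 1-D thin-plate equivalent), GCV lambda."""
    from scipy.interpolate import make_smoothing_spline

    spl = make_smoothing_spline(x, y)
    return np.asarray(spl(x))


def fit_trend(series: pd.Series, basis: str = "auto") -> TrendCurve:
    """Smooth one yearly abundance series and attach its 3-year derivatives.

    ``series`` is indexed by calendar year (already detection-trimmed).
    The cubic-regression-spline GAM is tried first; if it fails the
    thin-plate (smoothing-spline) basis is used instead and recorded in
    ``TrendCurve.basis``. Refitting the same series is deterministic.
    """
    series = series.dropna().sort_index()
    years = series.index.to_numpy(dtype=int)
    y = series.to_numpy(dtype=float)
    if len(y) < MIN_SERIES_LENGTH:
        raise InsufficientDataError(
            f"trend fitting needs >= {MIN_SERIES_LENGTH} yearly values, got {len(y)}"
        )
    x = (years - years[0]) / max(years[-1] - years[0], 1)

    fitted = None
    used = basis
    if basis in ("auto", "cubic-spline"):
        try:
            fitted = _fit_cubic_gam(x, y)
            used = "cubic-spline"
            if not np.all(np.isfinite(fitted)):
                raise FloatingPointError("non-finite GAM fit")
        except Exception:
            fitted = None
            if basis == "cubic-spline":
                raise
    if fitted is None:
        try:
            fitted = _fit_thin_plate(x, y)
            used = "thin-plate"
        except Exception as exc:
            raise RuntimeError(
                f"both spline bases failed for series starting {years[0]}"
            ) from exc

    deriv, danchor = _finite_differences(years, fitted)
    return TrendCurve(
        years=years, fitted=fitted, derivative=deriv, derivative_years=danchor,
        basis=used, trim_range=(int(years[0]), int(years[-1])),
    )


def _finite_differences(years: np.ndarray, fitted: np.ndarray):
    lut = dict(zip(years.tolist(), fitted.tolist()))
    anchors, deriv = [], []
    y0, y1 = years[0], years[-1]
    y = y0
    while y + STEP_YEARS <= y1:
        if y in lut and y + STEP_YEARS in lut:
            anchors.append(y)
            deriv.append(lut[y + STEP_YEARS] - lut[y])
        y += STEP_YEARS
    return np.asarray(deriv, dtype=float), np.asarray(anchors, dtype=int)


def derivative_series(curve: TrendCurve):
    """First differences of the fitted curve over consecutive 3-year windows.

    Positive values mean increasing abundance. A curve spanning less than
    one full 3-year step yields an empty series with a warning.
    """
    deriv, anchors = _finite_differences(curve.years, curve.fitted)
    if deriv.size == 0:
        warnings.warn("series shorter than one 3-year step; no derivatives",
                      stacklevel=2)
    return deriv, anchors


def classify_runs(derivatives: np.ndarray, derivative_years: np.ndarray | None = None,
                  dual: int = 5, decline: int = 15, increase: int = 8,
                  step_years: int = STEP_YEARS) -> RunClassification:
    """Maximal same-sign derivative runs and the non-stationarity flags.

    Each derivative step spans ``step_years`` years, so a run of ``r``
    consecutive same-sign steps lasts ``r * step_years`` years. Steps that
    are exactly zero (within 1e-12) break runs and count toward neither
    direction. Flags:

    * ``nonstationary`` — an increasing run >= ``dual`` years *and* a
      decreasing run >= ``dual`` years both occur;
    * ``decline15`` — some decreasing run lasts >= ``decline`` years;
    * ``increase8`` — some increasing run lasts >= ``increase`` years.
    """
    derivatives = np.asarray(derivatives, dtype=float)
    if derivatives.size == 0:
        raise ValueError("derivative series is empty; nothing to classify")
    if derivative_years is None:
        derivative_years = np.arange(derivatives.size) * step_years
    signs = np.where(derivatives > ZERO_TOL, 1,
                     np.where(derivatives < -ZERO_TOL, -1, 0))

    rows = []
    start = 0
    for i in range(1, signs.size + 1):
        if i == signs.size or signs[i] != signs[start]:
            if signs[start] != 0:
                rows.append({
                    "direction": "increasing" if signs[start] > 0 else "decreasing",
                    "start_year": int(derivative_years[start]),
                    "length_years": (i - start) * step_years,
                })
            start = i
    runs = pd.DataFrame(rows, columns=["direction", "start_year", "length_years"])

    inc = runs.loc[runs["direction"] == "increasing", "length_years"]
    dec = runs.loc[runs["direction"] == "decreasing", "length_years"]
    longest_inc = int(inc.max()) if len(inc) else 0
    longest_dec = int(dec.max()) if len(dec) else 0
    return RunClassification(
        runs=runs,
        nonstationary=bool(longest_inc >= dual and longest_dec >= dual),
        decline15=bool(longest_dec >= decline),
        increase8=bool(longest_inc >= increase),
    )


def classify_trend(curve: TrendCurve, **thresholds) -> RunClassification:
    """Run classification straight from a fitted :class:`TrendCurve`."""
    return classify_runs(curve.derivative, curve.derivative_years, **thresholds)


def circle_trend_matrix(estimates: AbundanceEstimate, panel=None,
                        min_years: int = MIN_SERIES_LENGTH):
    """Fit one trend per circle (the circle-by-species analysis).

    Returns ``(curves, skipped)`` where ``curves`` maps circle id to its
    :class:`TrendCurve`. When ``panel`` is given, each circle's series is
    trimmed to its own detection range first; circles with fewer than
    ``min_years`` usable years are skipped and listed.
    """
    curves, skipped = {}, []
    for circle, sub in estimates.table.groupby("circle"):
        series = sub.set_index("year")["mean"].sort_index()
        if panel is not None:
            i = int(np.flatnonzero(panel.circles == circle)[0])
            det = panel.years[(panel.counts[i] > 0) & np.isfinite(panel.counts[i])]
            if det.size == 0:
                skipped.append(circle)
                continue
            series = series[(series.index >= det.min()) & (series.index <= det.max())]
        if len(series) < min_years:
            skipped.append(circle)
            continue
        curves[circle] = fit_trend(series)
    return curves, skipped
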