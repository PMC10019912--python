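"""Core containers shared across the pipeline.

Tabular data travel as tidy :class:`pandas.DataFrame` objects (one row per
circle-year); the dense array view used by the sampler lives in
:class:`ObservationPanel`. Column conventions:

``circle``
    integer site identifier (a survey circle).
``year``
    calendar year of the count.
``count``
    number of individuals recorded (NaN where no usable survey exists).
``effort_hours``
    total party hours for the count (the sampling-effort covariate).
``interval_width``
    full width of the 2-SE prediction interval attached to an imputed
    effort value; exactly 0 where effort was recorded.
``min_temp``
    minimum daily temperature (deg C) on the count day.
``elevation``, ``habitat_area``, ``developed_area``, ``human_density``
    site covariates entering initial abundance, survival and recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

COVARIATE_NAMES = ("elevation", "habitat_area", "developed_area", "human_density")


class InvalidConfigError(ValueError):
    """Raised when a simulation or model configuration violates its invariants."""


class InsufficientDataError(ValueError):
    """Raised when an operation receives fewer data points than it requires."""


@dataclass
class DMMParams:
    """Regression coefficients of the single-visit Dail-Madsen model.

    Each of the three demographic blocks holds an intercept followed by
    slopes for (elevation, preferred-habitat area, developed area, human
    population density), applied to covariates standardized to mean 0, sd 1:

    * ``beta_lambda`` — log-linear model for the initial abundance rate
      ``Lambda_i1``:  ``N[i,1] ~ Poisson(Lambda_i1)``.
    * ``beta_omega`` — logit-linear model for apparent survival ``omega``:
      ``S[i,t] ~ Binomial(N[i,t-1], omega_it)``.
    * ``beta_gamma`` — log-linear model for per-capita recruitment ``gamma``:
      ``R[i,t] ~ Poisson(gamma_it * N[i,t-1])``.

    Detection is ``p = logistic(alpha0 + a_e * effort + a_m * min_temp)``
    with the sign constraints ``a_e > 0`` (more effort, higher detection)
    and ``a_m < 0`` (colder days, lower detection).
    """

    beta_lambda: np.ndarray
    beta_omega: np.ndarray
    beta_gamma: np.ndarray
    alpha0: float
    a_e: float
    a_m: float

    def __post_init__(self) -> None:
        self.beta_lambda = np.asarray(self.beta_lambda, dtype=float)
        self.beta_omega = np.asarray(self.beta_omega, dtype=float)
        self.beta_gamma = np.asarray(self.beta_gamma, dtype=float)
        for name in ("beta_lambda", "beta_omega", "beta_gamma"):
            vec = getattr(self, name)
            if vec.ndim != 1 or vec.size != 1 + len(COVARIATE_NAMES):
                raise InvalidConfigError(
                    f"{name} must be a vector of length {1 + len(COVARIATE_NAMES)} "
                    f"(intercept + {COVARIATE_NAMES}); got shape {vec.shape}"
                )
        if not self.a_e > 0:
            raise InvalidConfigError(f"effort slope a_e must be > 0, got {self.a_e}")
        if not self.a_m < 0:
            raise InvalidConfigError(f"temperature slope a_m must be < 0, got {self.a_m}")

    def to_vector(self) -> np.ndarray:
        """Flatten to the 18-vector used by the sampler (lambda, omega, gamma, alpha)."""
        return np.concatenate(
            [self.beta_lambda, self.beta_omega, self.beta_gamma,
             [self.alpha0, self.a_e, self.a_m]]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "DMMParams":
        vec = np.asarray(vec, dtype=float)
        k = 1 + len(COVARIATE_NAMES)
        return cls(
            beta_lambda=vec[:k],
            beta_omega=vec[k:2 * k],
            beta_gamma=vec[2 * k:3 * k],
            alpha0=float(vec[3 * k]),
            a_e=float(vec[3 * k + 1]),
            a_m=float(vec[3 * k + 2]),
        )

    @staticmethod
    def param_names() -> list[str]:
        slopes = ("intercept",) + COVARIATE_NAMES
        names = [f"beta_lambda[{s}]" for s in slopes]
        names += [f"beta_omega[{s}]" for s in slopes]
        names += [f"beta_gamma[{s}]" for s in slopes]
        names += ["alpha0", "a_e", "a_m"]
        return names


@dataclass
class LatentState:
    """Latent integer abundances underlying the observed counts.

    ``N[i, t]`` is true abundance at circle ``i`` in year index ``t``;
    for ``t >= 1``, ``S[i, t]`` survivors from ``t-1`` and ``R[i, t]``
    recruits satisfy ``N = S + R`` and ``S <= N[i, t-1]``. ``S[:, 0]`` and
    ``R[:, 0]`` are zero by convention (there is no transition into year 0).
    """

    N: np.ndarray
    S: np.ndarray
    R: np.ndarray

    def validate(self) -> None:
        N, S, R = self.N, self.S, self.R
        if not (N.shape == S.shape == R.shape):
            raise ValueError("N, S, R must share one (n_circles, n_years) shape")
        if np.any(N < 0) or np.any(S < 0) or np.any(R < 0):
            raise ValueError("latent abundances must be nonnegative")
        if N.shape[1] >= 2:
            if np.any(N[:, 1:] != S[:, 1:] + R[:, 1:]):
                raise ValueError("N[i,t] must equal S[i,t] + R[i,t] for t >= 1")
            if np.any(S[:, 1:] > N[:, :-1]):
                raise ValueError("survivors S[i,t] cannot exceed N[i,t-1]")


@dataclass
class ObservationPanel:
    """Dense circle x year panel for one species.

    ``counts`` is float with NaN marking circle-years without a usable
    survey; all other arrays are fully populated (effort may be imputed,
    in which case ``effort_width`` carries the prediction-interval width).
    """

    circles: np.ndarray          # (n,) circle ids
    years: np.ndarray            # (T,) calendar years
    counts: np.ndarray           # (n, T) float, NaN = not surveyed
    effort: np.ndarray           # (n, T) party hours, > 0
    effort_width: np.ndarray     # (n, T) 2-SE interval width, 0 where observed
    temp: np.ndarray             # (n, T) minimum temperature
    elevation: np.ndarray        # (n,)
    habitat_area: np.ndarray     # (n, T)
    developed_area: np.ndarray   # (n, T)
    human_density: np.ndarray    # (n, T)
    species: str = "species"

    @property
    def n_circles(self) -> int:
        return len(self.circles)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of circle-years with a recorded count."""
        return np.isfinite(self.counts)

    def validate(self) -> None:
        n, T = self.n_circles, self.n_years
        for name in ("counts", "effort", "effort_width", "temp",
                     "habitat_area", "developed_area", "human_density"):
            arr = getattr(self, name)
            if arr.shape != (n, T):
                raise ValueError(f"{name} must have shape {(n, T)}, got {arr.shape}")
        if self.elevation.shape != (n,):
            raise ValueError("elevation must be one value per circle")
        if np.any(self.effort <= 0):
            raise ValueError("effort must be strictly positive (party hours)")
        if np.any(self.effort_width < 0):
            raise ValueError("interval widths must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long view: one row per circle-year."""
        n, T = self.n_circles, self.n_years
        circle = np.repeat(self.circles, T)
        year = np.tile(self.years, n)
        return pd.DataFrame({
            "circle": circle,
            "year": year,
            "count": self.counts.ravel(),
            "effort_hours": self.effort.ravel(),
            "interval_width": self.effort_width.ravel(),
            "min_temp": self.temp.ravel(),
            "elevation": np.repeat(self.elevation, T),
            "habitat_area": self.habitat_area.ravel(),
            "developed_area": self.developed_area.ravel(),
            "human_density": self.human_density.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str = "species") -> "ObservationPanel":
        circles = np.sort(df["circle"].unique())
        years = np.sort(df["year"].unique())
        wide = df.set_index(["circle", "year"]).sort_index()
        full = pd.MultiIndex.from_product([circles, years], names=["circle", "year"])
        if not wide.index.equals(full):
            wide = wide.reindex(full)

        def grid(col: str) -> np.ndarray:
            return wide[col].to_numpy(dtype=float).reshape(len(circles), len(years))

        return cls(
            circles=circles,
            years=years,
            counts=grid("count"),
            effort=grid("effort_hours"),
            effort_width=grid("interval_width"),
            temp=grid("min_temp"),
            elevation=grid("elevation")[:, 0],
            habitat_area=grid("habitat_area"),
            developed_area=grid("developed_area"),
            human_density=grid("human_density"),
            species=species,
        )


@dataclass
class GammaCurveFit:
    """Scaled gamma-density curve fit to a circle's (year, party-hours) series."""

    amplitude: float
    shape: float
    scale: float
    onset_year: float
    residual_se: float
    n_points: int
    converged: bool = True
    sse: float = np.inf


@dataclass
class AbundanceEstimate:
    """Posterior summaries of latent abundance N per circle-year."""

    table: pd.DataFrame          # columns: circle, year, mean, lo95, hi95, ess
    yearly_mean: pd.Series       # region-wide mean of per-circle posterior means, by year


@dataclass
class TrendCurve:
    """Smoothed abundance trajectory with 3-year first-derivative steps."""

    years: np.ndarray            # yearly grid inside the detection-trimmed range
    fitted: np.ndarray           # smoothed abundance on that grid
    derivative: np.ndarray       # one value per 3-year step from the trimmed start
    derivative_years: np.ndarray  # start year of each 3-year step
    basis: str                   # "cubic-spline" or "thin-plate"
    trim_range: tuple            # (first_detection_year, last_detection_year)


@dataclass
class RunClassification:
    """Maximal same-sign derivative runs and the derived non-stationarity flags."""

    runs: pd.DataFrame           # columns: direction, start_year, length_years
    nonstationary: bool
    decline15: bool
    increase8: bool


@dataclass
class MedoidResult:
    """Outcome of partitioning around medoids on a trend-by-year matrix."""

    k: int
    medoid_indices: np.ndarray   # (k,) row indices of chosen medoids
    medoid_curves: np.ndarray    # (k, n_cols) representative standardized trends
    assignments: np.ndarray      # (n_rows,) labels in {0..k-1}
    total_cost: float            # sum of dissimilarities to assigned medoids
    method: str = "pam"


@dataclass
class CircleSummary:
    """Cluster-type composition of the species present at one circle."""

    circle: int
    counts: np.ndarray           # (k,) species per cluster label
    proportions: np.ndarray      # counts / total (zeros if total == 0)
    chi_square_stat: Optional[float]
    p_value: Optional[float]
    dominant_label: Optional[int]
    tested: bool
    guild: Optional[str] = None
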