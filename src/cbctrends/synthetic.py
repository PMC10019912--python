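"""Synthetic winter-count panels with the statistical structure the pipeline assumes.

Real Christmas Bird Count data are obtainable only through a data-request
portal, so every downstream stage is exercised on simulated panels that
emulate the features that matter for the analysis:

* a century of annual counts at a configurable number of survey circles;
* sampling effort (total party hours) whose mean follows a scaled
  gamma-density curve over years, with heavy missingness before 1967 and
  light missingness after;
* per-survey minimum temperature with a circle-level gradient;
* site covariates (static elevation; step-wise preferred-habitat area and
  developed area; decadal human population density);
* latent abundance evolving by the Dail-Madsen survival/recruitment
  dynamics, observed through effort- and temperature-driven detection;
* four smooth trend archetypes (steady decline, steady increase,
  increase-then-decline, flat-then-increase) for clustering tests.

All generators are deterministic given the configuration seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

from .dmm.likelihood import covariate_design, linear_predictors
from .types import (
    DMMParams,
    InvalidConfigError,
    LatentState,
    ObservationPanel,
)

EFFORT_CUTOVER_YEAR = 1967  # effort recording becomes routine from this year on


def default_dmm_params() -> DMMParams:
    """Sign-respecting coefficients producing near-stationary dynamics.

    Survival ~0.85 and per-capita recruitment ~0.15 sum to ~1, so typical
    populations hover around the initial abundance (exp(2.1) ~ 8 birds)
    over a century instead of exploding or crashing; demographic covariate
    effects are deliberately weak (|slope| <= 0.03) because their effect on
    the yearly growth rate compounds over 100 transitions. Initial
    abundance varies strongly across sites (slopes up to 0.4), which does
    not compound.
    """
    return DMMParams(
        beta_lambda=np.array([2.1, 0.3, 0.4, -0.3, -0.2]),
        beta_omega=np.array([1.735, 0.02, 0.03, -0.03, -0.015]),
        beta_gamma=np.array([-1.897, 0.015, 0.03, -0.03, -0.015]),
        alpha0=0.0,
        a_e=1.0,
        a_m=-0.5,
    )


def convergence_dmm_params() -> DMMParams:
    """Parameter set for convergence benchmarking on a multi-decade panel.

    Same near-stationary demography as :func:`default_dmm_params` but a
    higher abundance scale (Lambda ~ 30) with moderated spatial spread:
    binomial information about survival and detection grows with N, so
    this regime makes every coefficient estimable from a 20-circle,
    40-year panel while keeping counts in the low hundreds.
    """
    return DMMParams(
        beta_lambda=np.array([3.4, 0.2, 0.3, -0.2, -0.15]),
        beta_omega=np.array([1.735, 0.02, 0.03, -0.03, -0.015]),
        beta_gamma=np.array([-1.897, 0.015, 0.03, -0.03, -0.015]),
        alpha0=0.3,
        a_e=1.0,
        a_m=-0.5,
    )


def recovery_dmm_params() -> DMMParams:
    """Parameter set for coefficient-recovery studies on ~30-year panels.

    Demographic slopes are sized at roughly twice their posterior standard
    deviation at the 50-circle x 30-year study scale, so that sign
    recovery is a meaningful check rather than a coin flip: |0.1 - 0.12|
    for the time-varying covariates, and |0.2| for elevation, which is
    static per circle and therefore informs survival/recruitment only
    cross-sectionally (effective sample size = circles, not circle-years).
    Over three decades this compounding keeps counts below ~1000. The
    detection intercept is nonzero so its sign is defined.
    """
    return DMMParams(
        beta_lambda=np.array([1.8, 0.35, 0.25, -0.25, -0.2]),
        beta_omega=np.array([1.4, 0.2, 0.12, -0.12, -0.1]),
        beta_gamma=np.array([-1.5, 0.2, 0.12, -0.12, -0.1]),
        alpha0=0.3,
        a_e=1.0,
        a_m=-0.5,
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic species panel.

    Effort follows ``amplitude * gamma_pdf(year - onset; shape, scale)``
    with per-circle lognormal jitter on the amplitude and per-survey
    multiplicative lognormal noise, which keeps party hours strictly
    positive. Defaults put the effort peak around 2010 at roughly 60
    party hours, with about half of pre-1967 records missing and 96% of
    post-1967 records present.
    """

    n_circles: int = 20
    year_start: int = 1919
    year_end: int = 2018
    effort_amplitude: float = 7500.0
    effort_shape: float = 5.0
    effort_scale: float = 25.0
    effort_onset: float = 1910.0
    effort_amp_jitter: float = 0.15      # lognormal sd of per-circle amplitude
    effort_noise_sd: float = 0.10        # per-survey lognormal sigma
    missing_prob_pre1967: float = 0.5
    missing_prob_post1967: float = 0.04
    dmm_params: DMMParams = field(default_factory=default_dmm_params)
    temp_mean: float = -5.0              # deg C, mean of circle-level means
    temp_circle_sd: float = 5.0          # latitude-like spread across circles
    temp_survey_sd: float = 3.0          # year-to-year spread within a circle
    landcover_step: int = 5              # years between land-cover updates
    density_step: int = 10               # decadal human-density updates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_circles <= 0:
            raise InvalidConfigError(f"n_circles must be positive, got {self.n_circles}")
        if self.year_end <= self.year_start:
            raise InvalidConfigError("year_end must exceed year_start")
        for name in ("missing_prob_pre1967", "missing_prob_post1967"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("effort_amplitude", "effort_shape", "effort_scale"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Tidy covariate table: one row per circle-year.

    Elevation is static per circle. Habitat and developed areas follow
    step functions updated every ``landcover_step`` years (habitat drifts
    down, developed land drifts up, both clipped at zero); human density
    grows multiplicatively in ``density_step``-year (decadal) increments —
    between update years the most recent value is carried forward.
    """
    rng = _rng(config.seed, 1)
    years = config.years
    T = len(years)
    n = config.n_circles

    elevation = rng.uniform(0.0, 2500.0, size=n)

    def step_series(start_vals, drift, sd, step):
        anchors = np.arange(0, T, step)
        vals = np.empty((n, len(anchors)))
        vals[:, 0] = start_vals
        for j in range(1, len(anchors)):
            vals[:, j] = np.clip(vals[:, j - 1] + drift + rng.normal(0.0, sd, n), 0.0, None)
        idx = np.searchsorted(anchors, np.arange(T), side="right") - 1
        return vals[:, idx]

    habitat = step_series(rng.uniform(50.0, 300.0, n), -4.0, 6.0, config.landcover_step)
    developed = step_series(rng.uniform(5.0, 60.0, n), +3.0, 4.0, config.landcover_step)

    anchors = np.arange(0, T, config.density_step)
    dens = np.empty((n, len(anchors)))
    dens[:, 0] = rng.lognormal(3.0, 1.0, n)
    for j in range(1, len(anchors)):
        dens[:, j] = dens[:, j - 1] * rng.lognormal(0.15, 0.05, n)
    idx = np.searchsorted(anchors, np.arange(T), side="right") - 1
    density = dens[:, idx]

    return pd.DataFrame({
        "circle": np.repeat(np.arange(n), T),
        "year": np.tile(years, n),
        "elevation": np.repeat(elevation, T),
        "habitat_area": habitat.ravel(),
        "developed_area": developed.ravel(),
        "human_density": density.ravel(),
    })


def generate_effort(config: SimulationConfig) -> pd.DataFrame:
    """Party-hours table with a missingness mask.

    Columns: circle, year, effort_hours (true value, always present),
    missing (True where the record would be absent from the archive).
    Mean effort is the scaled gamma-density curve; noise is multiplicative
    lognormal. Pre-1967 and post-1967 years are masked independently with
    their configured probabilities.
    """
    rng = _rng(config.seed, 2)
    years = config.years
    T = len(years)
    n = config.n_circles

    amp = config.effort_amplitude * rng.lognormal(0.0, config.effort_amp_jitter, n)
    curve = gamma_dist.pdf(years - config.effort_onset,
                           a=config.effort_shape, scale=config.effort_scale)
    mean = amp[:, None] * curve[None, :]
    if config.effort_noise_sd > 0:
        noise = rng.lognormal(0.0, config.effort_noise_sd, (n, T))
    else:
        noise = 1.0
    effort = np.maximum(mean * noise, 0.1)

    pre = years < EFFORT_CUTOVER_YEAR
    p_missing = np.where(pre, config.missing_prob_pre1967, config.missing_prob_post1967)
    missing = rng.random((n, T)) < p_missing[None, :]

    return pd.DataFrame({
        "circle": np.repeat(np.arange(n), T),
        "year": np.tile(years, n),
        "effort_hours": effort.ravel(),
        "missing": missing.ravel(),
    })


def generate_temperature(config: SimulationConfig) -> pd.DataFrame:
    """Per-survey minimum temperature: circle-level normal means, survey noise."""
    rng = _rng(config.seed, 3)
    years = config.years
    n, T = config.n_circles, len(years)
    mu = rng.normal(config.temp_mean, config.temp_circle_sd, n)
    temp = mu[:, None] + rng.normal(0.0, config.temp_survey_sd, (n, T))
    return pd.DataFrame({
        "circle": np.repeat(np.arange(n), T),
        "year": np.tile(years, n),
        "min_temp": temp.ravel(),
    })


def _covariates_to_grids(covariates: pd.DataFrame):
    circles = np.sort(covariates["circle"].unique())
    years = np.sort(covariates["year"].unique())
    wide = covariates.set_index(["circle", "year"]).sort_index()

    def grid(col):
        return wide[col].to_numpy(dtype=float).reshape(len(circles), len(years))

    return circles, years, {
        "elevation": grid("elevation")[:, 0],
        "habitat_area": grid("habitat_area"),
        "developed_area": grid("developed_area"),
        "human_density": grid("human_density"),
    }


def simulate_dynamics(lam: np.ndarray, omega: np.ndarray, gamma: np.ndarray,
                      seed) -> LatentState:
    """Forward-simulate latent abundance from explicit per-circle-year rates.

    ``lam`` is (n,), ``omega`` and ``gamma`` (n, T); the rates are used as
    given (no clipping), so degenerate settings such as ``omega = 1,
    gamma = 0`` reproduce a frozen population exactly.
    """
    rng = np.random.default_rng(seed)
    n, T = omega.shape
    N = np.zeros((n, T), dtype=np.int64)
    S = np.zeros((n, T), dtype=np.int64)
    R = np.zeros((n, T), dtype=np.int64)
    N[:, 0] = rng.poisson(lam)
    for t in range(1, T):
        S[:, t] = rng.binomial(N[:, t - 1], omega[:, t])
        R[:, t] = rng.poisson(gamma[:, t] * N[:, t - 1])
        N[:, t] = S[:, t] + R[:, t]
    return LatentState(N=N, S=S, R=R)


def generate_latent_dynamics(params: DMMParams, covariates: pd.DataFrame,
                             seed) -> LatentState:
    """Simulate N, S, R from DMM coefficients applied to a covariate table.

    Covariates are standardized internally; rates are clipped after link
    inversion, matching the fitting model.
    """
    circles, years, grids = _covariates_to_grids(covariates)

    class _Cov:
        n_circles = len(circles)
        n_years = len(years)
        elevation = grids["elevation"]
        habitat_area = grids["habitat_area"]
        developed_area = grids["developed_area"]
        human_density = grids["human_density"]
        effort = np.ones((len(circles), len(years)))
        temp = np.zeros((len(circles), len(years)))
        observed = np.ones((len(circles), len(years)), dtype=bool)

    design = covariate_design(_Cov)
    lam, omega, gamma, _ = linear_predictors(
        params, design["Z"], design["effort_z"], design["temp_z"], check=False
    )
    return simulate_dynamics(lam, omega, gamma, seed)


def generate_observations(latent: LatentState, effort: pd.DataFrame,
                          temp: pd.DataFrame, detection_params, seed,
                          covariates: Optional[pd.DataFrame] = None,
                          p_fixed: Optional[float] = None,
                          species: str = "synthetic") -> ObservationPanel:
    """Thin the latent abundances into observed counts.

    ``X[i,t] ~ Binomial(N[i,t], p_it)`` at surveyed circle-years; the count
    is missing wherever the effort record is missing. Detection uses
    standardized effort and temperature (standardized over surveyed
    entries); ``p_fixed`` overrides the detection model with a constant
    (e.g. 1.0 for perfect detection in tests).

    The returned panel carries the *true* effort values with zero interval
    widths; archival missingness is expressed through the missing counts,
    and effort imputation is the effort module's job.
    """
    rng = np.random.default_rng(seed)
    n, T = latent.N.shape

    eff_wide = effort.pivot(index="circle", columns="year", values="effort_hours")
    eff = eff_wide.to_numpy(dtype=float)
    missing = (effort.pivot(index="circle", columns="year", values="missing")
               .to_numpy(dtype=bool))
    temp_arr = temp.pivot(index="circle", columns="year", values="min_temp").to_numpy(dtype=float)
    years = eff_wide.columns.to_numpy()
    if eff.shape != (n, T):
        raise ValueError("effort table not conformable with the latent state")

    surveyed = ~missing
    if p_fixed is not None:
        p = np.full((n, T), float(p_fixed))
    else:
        if isinstance(detection_params, DMMParams):
            alpha0, a_e, a_m = detection_params.alpha0, detection_params.a_e, detection_params.a_m
        else:
            alpha0, a_e, a_m = detection_params
        def zscore(x):
            vals = x[surveyed]
            sd = vals.std() if vals.std() > 1e-12 else 1.0
            return (x - vals.mean()) / sd
        p = expit(alpha0 + a_e * zscore(eff) + a_m * zscore(temp_arr))

    counts = np.where(surveyed, rng.binomial(latent.N, p), np.nan).astype(float)

    if covariates is not None:
        _, _, grids = _covariates_to_grids(covariates)
    else:
        grids = {
            "elevation": np.zeros(n),
            "habitat_area": np.zeros((n, T)),
            "developed_area": np.zeros((n, T)),
            "human_density": np.zeros((n, T)),
        }

    return ObservationPanel(
        circles=np.arange(n),
        years=years,
        counts=counts,
        effort=eff,
        effort_width=np.zeros((n, T)),
        temp=temp_arr,
        elevation=grids["elevation"],
        habitat_area=grids["habitat_area"],
        developed_area=grids["developed_area"],
        human_density=grids["human_density"],
        species=species,
    )


ARCHETYPE_NAMES = ("steady_decline", "steady_increase",
                   "increase_then_decline", "flat_then_increase")


def trend_archetypes(length: int) -> np.ndarray:
    """The four noiseless archetype shapes on a length-point grid, range [0, 1].

    1. steady decline, fastest early (convex exponential decay);
    2. steady increase (linear);
    3. rapid rise over the first half followed by steady decline (hump);
    4. flat until roughly the 55% mark, then steady increase (shifted logistic).
    """
    x = np.linspace(0.0, 1.0, length)
    shapes = np.vstack([
        np.exp(-2.5 * x),
        x,
        np.exp(-((x - 0.45) / 0.28) ** 2),
        expit(12.0 * (x - 0.55)),
    ])
    lo = shapes.min(axis=1, keepdims=True)
    hi = shapes.max(axis=1, keepdims=True)
    return (shapes - lo) / (hi - lo)


def generate_trend_archetypes(n_per_class: int, length: int, noise_sd: float,
                              seed):
    """Planted-trend matrix: ``n_per_class`` noisy copies of each archetype.

    Returns ``(matrix, labels)`` where ``labels[r]`` in {0..3} indexes
    :data:`ARCHETYPE_NAMES`. Noise is i.i.d. normal; each noiseless
    archetype spans [0, 1], so ``noise_sd = 0.1`` is 10% of signal range.
    """
    if n_per_class < 1:
        raise InvalidConfigError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    base = trend_archetypes(length)
    labels = np.repeat(np.arange(4), n_per_class)
    matrix = base[labels] + rng.normal(0.0, noise_sd, (labels.size, length))
    return matrix, labels


def apply_study_filters(panel: ObservationPanel, min_circle_samplings: int = 30,
                        min_species_detections: int = 10):
    """Drop under-sampled circles and circles where the species is rare.

    A circle is removed when it was sampled (has a recorded count) fewer
    than ``min_circle_samplings`` times, or when the species was detected
    (count > 0) fewer than ``min_species_detections`` times there; circles
    exactly at a threshold are retained. Returns the filtered panel and a
    report dict with removal counts.
    """
    obs = panel.observed
    samplings = obs.sum(axis=1)
    detections = np.nansum(panel.counts > 0, axis=1)
    undersampled = samplings < min_circle_samplings
    rare = detections < min_species_detections
    keep = ~(undersampled | rare)
    report = {
        "n_input": panel.n_circles,
        "removed_undersampled": int(undersampled.sum()),
        "removed_rare": int((rare & ~undersampled).sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("study filters removed every circle; returning an empty panel",
                      stacklevel=2)
    idx = np.flatnonzero(keep)
    filtered = ObservationPanel(
        circles=panel.circles[idx],
        years=panel.years,
        counts=panel.counts[idx],
        effort=panel.effort[idx],
        effort_width=panel.effort_width[idx],
        temp=panel.temp[idx],
        elevation=panel.elevation[idx],
        habitat_area=panel.habitat_area[idx],
        developed_area=panel.developed_area[idx],
        human_density=panel.human_density[idx],
        species=panel.species,
    )
    return filtered, report


@dataclass
class SimulationResult:
    """Everything one synthetic species run produces."""

    panel: ObservationPanel          # counts masked by archival missingness
    latent: LatentState              # true N, S, R
    effort_table: pd.DataFrame       # true effort + missing mask (imputation input)
    covariates: pd.DataFrame
    temperature: pd.DataFrame
    config: SimulationConfig


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: covariates, effort, temperature, dynamics, counts."""
    covs = generate_covariates(config)
    eff = generate_effort(config)
    temp = generate_temperature(config)
    latent = generate_latent_dynamics(config.dmm_params, covs,
                                      np.random.SeedSequence([config.seed, 4]))
    panel = generate_observations(latent, eff, temp, config.dmm_params,
                                  np.random.SeedSequence([config.seed, 5]),
                                  covariates=covs)
    return SimulationResult(panel=panel, latent=latent, effort_table=eff,
                            covariates=covs, temperature=temp, config=config)
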