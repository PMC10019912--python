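"""Tidy CSV input/output for simulation and analysis tables.

A simulated study is stored as a directory of plain CSV files (one row
per circle-year) plus a key-value metadata file:

* ``counts.csv`` — circle, year, count (blank where not surveyed)
* ``effort.csv`` — circle, year, effort_hours, missing
* ``temperature.csv`` — circle, year, min_temp (deg C)
* ``covariates.csv`` — circle, year, elevation (m), habitat_area,
  developed_area (area units), human_density (persons per area unit)
* ``metadata.yaml`` — the simulation configuration, including the seed
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SimulationConfig, SimulationResult, default_dmm_params
from .types import DMMParams, ObservationPanel


def write_simulation(result: SimulationResult, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = result.panel
    counts = panel.to_frame()[["circle", "year", "count"]]
    counts.to_csv(out / "counts.csv", index=False)
    result.effort_table.to_csv(out / "effort.csv", index=False)
    result.temperature.to_csv(out / "temperature.csv", index=False)
    result.covariates.to_csv(out / "covariates.csv", index=False)

    cfg = asdict(result.config)
    cfg["dmm_params"] = {
        "beta_lambda": result.config.dmm_params.beta_lambda.tolist(),
        "beta_omega": result.config.dmm_params.beta_omega.tolist(),
        "beta_gamma": result.config.dmm_params.beta_gamma.tolist(),
        "alpha0": result.config.dmm_params.alpha0,
        "a_e": result.config.dmm_params.a_e,
        "a_m": result.config.dmm_params.a_m,
    }
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "dmm_params" in raw and isinstance(raw["dmm_params"], dict):
        raw["dmm_params"] = DMMParams(**raw["dmm_params"])
    elif "dmm_params" not in raw:
        raw["dmm_params"] = default_dmm_params()
    return SimulationConfig(**raw)


def read_panel(sim_dir, effort_imputed: pd.DataFrame | None = None,
               species: str = "synthetic") -> ObservationPanel:
    """Assemble an :class:`ObservationPanel` from a simulation directory.

    When ``effort_imputed`` (output of the effort module, with
    ``interval_width``) is given, it supplies complete effort values;
    otherwise the stored true effort is used with zero widths.
    """
    d = Path(sim_dir)
    counts = pd.read_csv(d / "counts.csv")
    temp = pd.read_csv(d / "temperature.csv")
    covs = pd.read_csv(d / "covariates.csv")
    if effort_imputed is not None:
        eff = effort_imputed[["circle", "year", "effort_hours", "interval_width"]]
    else:
        eff = pd.read_csv(d / "effort.csv")[["circle", "year", "effort_hours"]].copy()
        eff["interval_width"] = 0.0
    df = counts.merge(eff, on=["circle", "year"]).merge(temp, on=["circle", "year"])
    df = df.merge(covs, on=["circle", "year"])
    return ObservationPanel.from_frame(df, species=species)
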