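"""Shared fixtures: tiny panels and reference parameter sets.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from cbctrends.types import DMMParams, ObservationPanel


def make_panel(X, effort=None, effort_width=None, temp=None) -> ObservationPanel:
    """Minimal panel around a count matrix; constant unit effort, zero temp.

    Constant covariate columns standardize to exactly zero, so intercept-only
    parameter sets give closed-form rates (e.g. p = logistic(alpha0)).
    """
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    return ObservationPanel(
        circles=np.arange(n),
        years=np.arange(2000, 2000 + T),
        counts=X,
        effort=np.ones((n, T)) if effort is None else np.asarray(effort, float),
        effort_width=(np.zeros((n, T)) if effort_width is None
                      else np.asarray(effort_width, float)),
        temp=np.zeros((n, T)) if temp is None else np.asarray(temp, float),
        elevation=np.zeros(n),
        habitat_area=np.zeros((n, T)),
        developed_area=np.zeros((n, T)),
        human_density=np.zeros((n, T)),
    )


@pytest.fixture
def intercept_params() -> DMMParams:
    """Intercept-only coefficients: Lambda=2, omega=0.6, gamma=0.4, p=logistic(0.5)."""
    return DMMParams(
        beta_lambda=[np.log(2.0), 0, 0, 0, 0],
        beta_omega=[np.log(0.6 / 0.4), 0, 0, 0, 0],
        beta_gamma=[np.log(0.4), 0, 0, 0, 0],
        alpha0=0.5,
        a_e=0.5,
        a_m=-0.5,
    )


@pytest.fixture
def rising_panel() -> ObservationPanel:
    """2 sites x 3 years with counts <= 5 rising from zero.

    Rising counts cannot be explained by survival alone, so the recruitment
    coefficient is well identified and its posterior has a negligible
    low-gamma tail — important for grid-based oracle comparisons.
    """
    return make_panel([[0, 2, 5], [1, 0, 4]])
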