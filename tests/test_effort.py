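"""Effort imputation: gamma-curve fits, loess smoothing, series assembly."""

import numpy as np
import pandas as pd
import pytest

from cbctrends import effort as ef
from cbctrends.types import InsufficientDataError

TRUE = dict(amplitude=7500.0, shape=5.0, scale=25.0, onset_year=1910.0)


def noiseless_series(y0=1919, y1=1990):
    years = np.arange(y0, y1)
    return years, ef.gamma_curve(years, **TRUE)


class TestGammaCurveFit:
    def test_noiseless_parameters_recovered_within_one_percent(self):
        years, hours = noiseless_series()
        fit = ef.fit_effort_curve(years, hours)
        assert fit.converged
        for name, val in TRUE.items():
            assert abs(getattr(fit, name) - val) / abs(val) < 0.01

    def test_residual_se_near_zero_on_noiseless_data(self):
        years, hours = noiseless_series()
        fit = ef.fit_effort_curve(years, hours)
        assert fit.residual_se < 1e-6

    def test_three_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            ef.fit_effort_curve(np.array([1950, 1960, 1970]),
                                np.array([1.0, 2.0, 3.0]))

    def test_constant_hours_never_crashes(self):
        years = np.arange(1950, 1990)
        fit = ef.fit_effort_curve(years, np.full(years.size, 12.0))
        # near-flat fit or flagged non-convergence are both acceptable
        if fit.converged:
            pred = ef.predict_effort(fit, years)["effort_hours"]
            assert np.all(np.isfinite(pred))

    def test_nonpositive_hours_rejected(self):
        years = np.arange(1950, 1960)
        with pytest.raises(ValueError):
            ef.fit_effort_curve(years, np.zeros(years.size))


class TestPredictEffort:
    def test_zero_residual_se_means_zero_width(self):
        years, hours = noiseless_series()
        fit = ef.fit_effort_curve(years, hours)
        out = ef.predict_effort(fit, np.array([1930.0, 1950.0]))
        np.testing.assert_allclose(out["interval_width"], 0.0, atol=1e-5)

    def test_prediction_at_training_year_matches_observation(self):
        years, hours = noiseless_series()
        fit = ef.fit_effort_curve(years, hours)
        out = ef.predict_effort(fit, years)
        np.testing.assert_allclose(out["effort_hours"], hours, rtol=1e-4)

    def test_width_equals_upper_minus_lower(self):
        years, hours = noiseless_series()
        rng = np.random.default_rng(0)
        fit = ef.fit_effort_curve(years, hours * rng.lognormal(0, 0.1, years.size))
        out = ef.predict_effort(fit, np.array([1940.0, 1960.0]))
        # away from the positivity floor, width = upper - lower = 4 SE
        np.testing.assert_allclose(out["interval_width"],
                                   out["upper"] - out["lower"], rtol=1e-12)
        np.testing.assert_allclose(out["interval_width"], 4 * fit.residual_se,
                                   rtol=1e-12)


class TestSmoothEffort:
    def test_linear_data_reproduced(self):
        years = np.arange(1968, 2019).astype(float)
        hours = 2.0 * (years - 1968) + 5.0
        out = ef.smooth_effort(years, hours, np.array([1975.0, 1990.5, 2010.0]))
        expected = 2.0 * (out["year"].to_numpy() - 1968) + 5.0
        np.testing.assert_allclose(out["effort_hours"], expected, rtol=1e-6)

    def test_no_target_years_gives_empty_output(self):
        years = np.arange(1968, 2019).astype(float)
        out = ef.smooth_effort(years, years, np.array([]))
        assert len(out) == 0

    def test_extrapolation_refused(self):
        years = np.arange(1968, 2019).astype(float)
        out = ef.smooth_effort(years, years, np.array([1950.0, 1990.0, 2030.0]))
        assert list(out["year"]) == [1990.0]

    def test_duplicated_point_shifts_prediction_less_than_se(self):
        rng = np.random.default_rng(1)
        years = np.arange(1968, 2019).astype(float)
        hours = 30 + 0.5 * (years - 1968) + rng.normal(0, 1.0, years.size)
        targets = np.array([1980.0, 2000.0])
        base = ef.smooth_effort(years, hours, targets)
        years2 = np.append(years, 1985.0)
        hours2 = np.append(hours, hours[years == 1985.0][0])
        dup = ef.smooth_effort(years2, hours2, targets)
        shift = np.abs(base["effort_hours"].to_numpy() - dup["effort_hours"].to_numpy())
        se = base["interval_width"].to_numpy() / 4.0
        assert np.all(shift <= np.maximum(se, 1e-9))

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            ef.smooth_effort(np.arange(5.0), np.arange(5.0), np.array([2.0]))


class TestAssembleEffort:
    def _observed(self, years, hours):
        return pd.DataFrame({"year": years, "effort_hours": hours})

    def test_fully_observed_passthrough(self):
        years = np.arange(1919, 2019)
        hours = ef.gamma_curve(years, **TRUE)
        out = ef.assemble_effort(self._observed(years, hours), None, (1919, 2018))
        assert (out["source"] == "observed").all()
        assert (out["interval_width"] == 0).all()
        np.testing.assert_allclose(out["effort_hours"], hours[:100])

    def test_pre1967_gaps_gamma_imputed(self):
        years = np.arange(1919, 2019)
        hours = ef.gamma_curve(years, **TRUE)
        keep = years >= 1967
        fit = ef.fit_effort_curve(years[keep], hours[keep])
        out = ef.assemble_effort(self._observed(years[keep], hours[keep]), fit,
                                 (1919, 2018))
        pre = out[out["year"] < 1967]
        assert (pre["source"] == "gamma-imputed").all()
        assert (pre["interval_width"] >= 0).all()

    def test_one_row_per_year_exhaustive(self):
        years = np.arange(1919, 2019)
        hours = ef.gamma_curve(years, **TRUE)
        rng = np.random.default_rng(2)
        keep = rng.random(years.size) > 0.3
        keep[years >= 1967] |= rng.random((years >= 1967).sum()) > 0.1
        fit = ef.fit_effort_curve(years[keep], hours[keep])
        out = ef.assemble_effort(self._observed(years[keep], hours[keep]), fit,
                                 (1919, 2018))
        assert sorted(out["year"].tolist()) == list(range(1919, 2019))
        assert len(out) == 100
        assert out["effort_hours"].notna().all()

    def test_observed_values_never_altered(self):
        years = np.arange(1940, 2019)
        hours = ef.gamma_curve(years, **TRUE) * 1.07  # off-curve observations
        fit = ef.fit_effort_curve(years, hours)
        out = ef.assemble_effort(self._observed(years, hours), fit, (1919, 2018))
        merged = out[out["year"].isin(years)]
        np.testing.assert_allclose(merged["effort_hours"].to_numpy(), hours)
        assert (merged["interval_width"] == 0).all()


class TestImputePanel:
    def test_panel_round_trip_with_mask(self):
        from cbctrends import synthetic as syn

        cfg = syn.SimulationConfig(n_circles=3, seed=13)
        eff = syn.generate_effort(cfg)
        out = ef.impute_effort_panel(eff)
        assert len(out) == 3 * 100
        obs = out["source"] == "observed"
        assert (out.loc[obs, "interval_width"] == 0).all()
        assert (out.loc[~obs, "interval_width"] >= 0).all()
        assert (out["effort_hours"] > 0).all()

    def test_low_noise_imputation_accuracy(self):
        """With noise sd -> 0 the imputed values converge to the true curve."""
        from cbctrends import synthetic as syn

        cfg = syn.SimulationConfig(n_circles=2, effort_noise_sd=0.0,
                                   effort_amp_jitter=0.0,
                                   missing_prob_pre1967=0.4,
                                   missing_prob_post1967=0.04, seed=14)
        eff = syn.generate_effort(cfg)
        out = ef.impute_effort_panel(eff)
        truth = eff.set_index(["circle", "year"])["effort_hours"]
        imputed = out[out["source"] != "observed"]
        for _, row in imputed.iterrows():
            true_val = truth.loc[(row["circle"], row["year"])]
            if true_val > 1.0:  # relative error is meaningful away from the floor
                assert abs(row["effort_hours"] - true_val) / true_val < 0.01
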