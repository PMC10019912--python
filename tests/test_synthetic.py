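"""Generator contracts: determinism, step structure, dynamics moments, filters."""

import numpy as np
import pandas as pd
import pytest

from cbctrends import synthetic as syn
from cbctrends.types import InvalidConfigError, ObservationPanel
from tests.conftest import make_panel


class TestCovariates:
    def test_same_seed_gives_identical_tables(self):
        cfg = syn.SimulationConfig(n_circles=4, seed=42)
        a = syn.generate_covariates(cfg)
        b = syn.generate_covariates(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = syn.generate_covariates(syn.SimulationConfig(n_circles=4, seed=1))
        b = syn.generate_covariates(syn.SimulationConfig(n_circles=4, seed=2))
        assert not a.equals(b)

    def test_density_constant_within_decade(self):
        """Decadal human density: brute-force scan of every circle-year."""
        cfg = syn.SimulationConfig(n_circles=3, year_start=1919, year_end=2018,
                                   density_step=10, seed=3)
        covs = syn.generate_covariates(cfg)
        for circle, sub in covs.groupby("circle"):
            sub = sub.sort_values("year")
            decade = (sub["year"] - cfg.year_start) // 10
            for _, grp in sub.groupby(decade):
                assert grp["human_density"].nunique() == 1

    def test_landcover_steps_only_at_step_years(self):
        cfg = syn.SimulationConfig(n_circles=2, landcover_step=5, seed=4)
        covs = syn.generate_covariates(cfg)
        for _, sub in covs.groupby("circle"):
            sub = sub.sort_values("year").reset_index(drop=True)
            changes = np.flatnonzero(np.diff(sub["habitat_area"].to_numpy()) != 0) + 1
            assert all((c % 5) == 0 for c in changes)

    def test_covariates_complete_and_nonnegative(self):
        cfg = syn.SimulationConfig(n_circles=5, seed=5)
        covs = syn.generate_covariates(cfg)
        assert len(covs) == 5 * len(cfg.years)
        assert not covs.isna().any().any()
        for col in ("habitat_area", "developed_area", "human_density"):
            assert (covs[col] >= 0).all()

    def test_invalid_circle_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            syn.SimulationConfig(n_circles=0)


class TestLatentDynamics:
    def test_frozen_population_when_survival_one(self):
        n, T = 6, 10
        lam = np.full(n, 5.0)
        latent = syn.simulate_dynamics(lam, np.ones((n, T)), np.zeros((n, T)), seed=0)
        assert np.all(latent.N == latent.N[:, [0]])

    def test_extinction_when_both_rates_zero(self):
        n, T = 6, 10
        latent = syn.simulate_dynamics(np.full(n, 5.0), np.zeros((n, T)),
                                       np.zeros((n, T)), seed=0)
        assert np.all(latent.N[:, 1:] == 0)

    def test_growth_rate_matches_omega_plus_gamma(self):
        """Mean one-step growth over many replicate sites ~ omega + gamma."""
        n, T = 10_000, 2
        omega, gamma = 0.7, 0.4
        lam = np.full(n, 20.0)
        latent = syn.simulate_dynamics(lam, np.full((n, T), omega),
                                       np.full((n, T), gamma), seed=1)
        ratio = latent.N[:, 1] / latent.N[:, 0]
        # Var(N_t/N_prev | N_prev) = (omega(1-omega) + gamma)/N_prev
        mc_se = np.sqrt((omega * (1 - omega) + gamma) / 20.0 / n)
        assert abs(ratio.mean() - (omega + gamma)) < 3 * mc_se

    def test_conservation_invariants(self):
        cfg = syn.SimulationConfig(n_circles=8, seed=11)
        covs = syn.generate_covariates(cfg)
        latent = syn.generate_latent_dynamics(cfg.dmm_params, covs, seed=2)
        latent.validate()  # N = S + R and S <= N_prev

    def test_recruitment_dispersion_is_poisson(self):
        """Var/mean of R at fixed N matches the Poisson ratio of 1."""
        n = 20_000
        gamma, N0 = 0.5, 30.0
        latent = syn.simulate_dynamics(np.full(n, N0), np.full((n, 2), 0.0),
                                       np.full((n, 2), gamma), seed=3)
        # N0 is Poisson(30) here, so condition by regressing out N_prev
        R = latent.R[:, 1]
        mu = gamma * latent.N[:, 0]
        standardized = (R - mu)
        ratio = standardized.var() / mu.mean()
        assert abs(ratio - 1.0) < 0.05


class TestObservations:
    def _tables(self, n, T, missing=None):
        years = np.arange(2000, 2000 + T)
        eff = pd.DataFrame({
            "circle": np.repeat(np.arange(n), T),
            "year": np.tile(years, n),
            "effort_hours": 10.0,
            "missing": False if missing is None else np.asarray(missing).ravel(),
        })
        temp = pd.DataFrame({
            "circle": np.repeat(np.arange(n), T),
            "year": np.tile(years, n),
            "min_temp": -5.0,
        })
        return eff, temp

    def test_perfect_detection_returns_latent(self):
        n, T = 4, 6
        latent = syn.simulate_dynamics(np.full(n, 8.0), np.full((n, T), 0.8),
                                       np.full((n, T), 0.2), seed=4)
        eff, temp = self._tables(n, T)
        panel = syn.generate_observations(latent, eff, temp, None, seed=5, p_fixed=1.0)
        assert np.array_equal(panel.counts.astype(int), latent.N)

    def test_zero_detection_gives_zero_counts(self):
        n, T = 4, 6
        latent = syn.simulate_dynamics(np.full(n, 8.0), np.full((n, T), 0.8),
                                       np.full((n, T), 0.2), seed=4)
        eff, temp = self._tables(n, T)
        panel = syn.generate_observations(latent, eff, temp, None, seed=5, p_fixed=0.0)
        assert np.all(panel.counts == 0)

    def test_counts_missing_where_effort_missing(self):
        n, T = 3, 8
        rng = np.random.default_rng(0)
        missing = rng.random((n, T)) < 0.4
        latent = syn.simulate_dynamics(np.full(n, 8.0), np.full((n, T), 0.8),
                                       np.full((n, T), 0.2), seed=4)
        eff, temp = self._tables(n, T, missing=missing)
        panel = syn.generate_observations(latent, eff, temp, (0.0, 1.0, -0.5), seed=5)
        assert np.array_equal(np.isnan(panel.counts), missing)

    def test_binomial_mean_at_half_detection(self):
        """10,000 replicate surveys of N=100 at p=0.5: mean X ~ 50."""
        n = 10_000
        from cbctrends.types import LatentState
        N = np.full((n, 1), 100, dtype=np.int64)
        latent = LatentState(N=N, S=np.zeros_like(N), R=np.zeros_like(N))
        eff, temp = self._tables(n, 1)
        panel = syn.generate_observations(latent, eff, temp, None, seed=6, p_fixed=0.5)
        mc_se = np.sqrt(100 * 0.25 / n)
        assert abs(np.nanmean(panel.counts) - 50.0) < 3 * mc_se

    def test_counts_never_exceed_latent(self):
        cfg = syn.SimulationConfig(n_circles=6, seed=12)
        res = syn.simulate(cfg)
        obs = np.isfinite(res.panel.counts)
        assert np.all(res.panel.counts[obs] <= res.latent.N[obs])


class TestEffortGeneration:
    def test_all_pre1967_masked_at_probability_one(self):
        cfg = syn.SimulationConfig(n_circles=3, missing_prob_pre1967=1.0,
                                   missing_prob_post1967=0.0, seed=7)
        eff = syn.generate_effort(cfg)
        pre = eff[eff["year"] < syn.EFFORT_CUTOVER_YEAR]
        post = eff[eff["year"] >= syn.EFFORT_CUTOVER_YEAR]
        assert pre["missing"].all()
        assert not post["missing"].any()

    def test_zero_noise_reproduces_curve_exactly(self):
        cfg = syn.SimulationConfig(n_circles=2, effort_noise_sd=0.0,
                                   effort_amp_jitter=0.0, seed=8)
        eff = syn.generate_effort(cfg)
        from scipy.stats import gamma as gamma_dist
        years = eff["year"].to_numpy()
        expected = np.maximum(
            cfg.effort_amplitude * gamma_dist.pdf(years - cfg.effort_onset,
                                                  a=cfg.effort_shape,
                                                  scale=cfg.effort_scale),
            0.1,
        )
        np.testing.assert_allclose(eff["effort_hours"].to_numpy(), expected, rtol=1e-12)

    def test_masked_fraction_matches_probabilities(self):
        cfg = syn.SimulationConfig(n_circles=60, missing_prob_pre1967=0.5,
                                   missing_prob_post1967=0.04, seed=9)
        eff = syn.generate_effort(cfg)
        pre = eff[eff["year"] < syn.EFFORT_CUTOVER_YEAR]["missing"]
        post = eff[eff["year"] >= syn.EFFORT_CUTOVER_YEAR]["missing"]
        for frac, p, n in ((pre.mean(), 0.5, len(pre)), (post.mean(), 0.04, len(post))):
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestTrendArchetypes:
    def test_noiseless_rows_equal_archetypes(self):
        matrix, labels = syn.generate_trend_archetypes(1, 50, 0.0, seed=0)
        np.testing.assert_allclose(matrix, syn.trend_archetypes(50))
        assert np.array_equal(labels, np.arange(4))

    def test_labels_balanced(self):
        _, labels = syn.generate_trend_archetypes(7, 30, 0.1, seed=1)
        assert np.array_equal(np.bincount(labels), np.full(4, 7))

    def test_nearest_template_recovery_at_low_noise(self):
        """Brute-force nearest-archetype classification recovers >= 99% of labels."""
        matrix, labels = syn.generate_trend_archetypes(250, 100, 0.1, seed=2)
        base = syn.trend_archetypes(100)
        d = ((matrix[:, None, :] - base[None, :, :]) ** 2).sum(axis=2)
        recovered = d.argmin(axis=1)
        assert (recovered == labels).mean() >= 0.99


class TestStudyFilters:
    def _panel_with_sampling_counts(self, sampling_counts, T=100):
        n = len(sampling_counts)
        counts = np.full((n, T), np.nan)
        rng = np.random.default_rng(0)
        for i, c in enumerate(sampling_counts):
            idx = rng.choice(T, size=c, replace=False)
            counts[i, idx] = 1.0  # every sampling detects the species
        return make_panel(counts)

    def test_exactly_thirty_samplings_retained(self):
        panel = self._panel_with_sampling_counts([30])
        filtered, report = syn.apply_study_filters(panel)
        assert filtered.n_circles == 1
        assert report["removed_undersampled"] == 0

    def test_toy_panel_counts_removed_by_hand_enumeration(self):
        """Sampling counts {10, 29, 30, 31, 100}: exactly the first two go."""
        panel = self._panel_with_sampling_counts([10, 29, 30, 31, 100])
        filtered, report = syn.apply_study_filters(panel)
        assert report["removed_undersampled"] == 2
        assert filtered.n_circles == 3
        assert np.array_equal(filtered.circles, [2, 3, 4])

    def test_all_above_thresholds_identity(self):
        panel = self._panel_with_sampling_counts([40, 50, 60])
        filtered, _ = syn.apply_study_filters(panel)
        np.testing.assert_array_equal(filtered.counts, panel.counts)

    def test_rare_species_circle_removed(self):
        counts = np.zeros((2, 100))
        counts[0, :50] = 1.0   # 50 detections
        counts[1, :9] = 1.0    # 9 detections, 100 samplings
        panel = make_panel(counts)
        filtered, report = syn.apply_study_filters(panel)
        assert report["removed_rare"] == 1
        assert filtered.n_circles == 1

    def test_empty_result_warns_not_raises(self):
        panel = self._panel_with_sampling_counts([5, 5])
        with pytest.warns(UserWarning, match="empty"):
            filtered, _ = syn.apply_study_filters(panel)
        assert filtered.n_circles == 0


def test_full_simulation_deterministic_and_consistent():
    cfg = syn.SimulationConfig(n_circles=5, year_start=1959, year_end=2018, seed=21)
    a = syn.simulate(cfg)
    b = syn.simulate(cfg)
    np.testing.assert_array_equal(a.panel.counts, b.panel.counts)
    np.testing.assert_array_equal(a.latent.N, b.latent.N)
    pd.testing.assert_frame_equal(a.effort_table, b.effort_table)
    a.panel.validate()
    a.latent.validate()
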