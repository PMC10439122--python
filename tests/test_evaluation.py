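"""Survey processing, KDE class fitting, Gini/Lorenz, chi-squared, KS and
flux comparison statistics, each checked against an independent brute-force
oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprucestand import (
    SurveyData,
    chi_squared_classes,
    fit_kde_to_classes,
    flux_error_stats,
    gen_survey,
    gini_biomass,
    gini_from_classes,
    initialise_from_distribution,
    ks_statistic,
    mass_from_dbh,
    seasonal_diurnal_matrix,
    stand_aggregates,
    survey_to_masses,
    truncation_mass,
)


def gini_pairwise_oracle(x, w=None):
    """O(n^2) mean-absolute-difference Gini."""
    x = np.asarray(x, dtype=float)
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, dtype=float)
    num = np.sum(w[:, None] * w[None, :] * np.abs(x[:, None] - x[None, :]))
    wx = np.sum(w * x)
    return num / (2.0 * w.sum() * wx)


class TestSurveyProcessing:
    def test_density_scale_from_plot_geometry(self):
        survey = SurveyData(((8,),) * 10, plot_area_m2=200.0)
        _, scale = survey_to_masses(survey)
        assert scale == pytest.approx(5.0)  # 10000 / (10 * 200)

    def test_total_density_of_270_trees(self):
        plots = tuple(tuple([10] * 27) for _ in range(10))
        survey = SurveyData(plots, plot_area_m2=200.0)
        masses, scale = survey_to_masses(survey)
        assert len(masses) * scale == pytest.approx(1350.0)

    def test_minimum_dbh_maps_to_truncation_mass(self, allom):
        survey = SurveyData(((7,),), plot_area_m2=200.0)
        masses, _ = survey_to_masses(survey, allom)
        assert masses[0] == pytest.approx(truncation_mass(7.0, allom), rel=1e-12)

    def test_below_minimum_trees_dropped_with_warning(self):
        survey = SurveyData(((5, 10),), plot_area_m2=200.0)
        with pytest.warns(UserWarning):
            masses, _ = survey_to_masses(survey)
        assert len(masses) == 1


class TestKdeFit:
    def test_total_density_preserved_exactly(self, grid):
        rng = np.random.default_rng(0)
        masses = np.exp(rng.normal(4.5, 0.5, 150))
        dens = fit_kde_to_classes(masses, 5.0, grid)
        assert dens.sum() == pytest.approx(150 * 5.0, rel=1e-12)

    def test_single_mass_falls_back_to_direct_binning(self, grid):
        with pytest.warns(UserWarning):
            dens = fit_kde_to_classes(np.array([20.0]), 5.0, grid)
        assert dens[grid.class_of_mass(20.0)] == pytest.approx(5.0)
        assert dens.sum() == pytest.approx(5.0)

    def test_symmetric_masses_give_symmetric_densities(self, grid):
        # two equal-weight masses at the centres of classes 3 and 5: the
        # log-mass KDE is symmetric about class 4's centre
        masses = np.array([grid.class_masses[3], grid.class_masses[5]])
        dens = fit_kde_to_classes(masses, 1.0, grid)
        assert dens[3] == pytest.approx(dens[5], rel=1e-9)
        assert dens[2] == pytest.approx(dens[6], rel=1e-9)

    def test_fitted_state_reproduces_survey_density_above_truncation(
        self, grid, allom, pft
    ):
        survey = gen_survey(seed=3)
        masses, scale = survey_to_masses(survey, allom)
        dens = fit_kde_to_classes(masses, scale, grid)
        state = initialise_from_distribution(grid, dens, stand_age=45.0)
        agg = stand_aggregates(state, grid, truncation_mass(7.0, allom), pft)
        total = len(masses) * scale
        assert abs(agg.n_density_ha - total) / total < 0.01


class TestGini:
    def test_equal_masses_give_zero(self):
        assert gini_biomass(np.full(100, 7.0)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "masses, expected",
        [([0.0, 1.0], 0.5), ([1.0, 2.0, 3.0], 2.0 / 9.0)],
    )
    def test_small_hand_checked_cases(self, masses, expected):
        assert gini_biomass(masses) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(min_value=2, max_value=60), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40)
    def test_matches_pairwise_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 50.0, n) + 1e-6
        assert gini_biomass(x) == pytest.approx(gini_pairwise_oracle(x), abs=1e-12)

    def test_weighted_form_matches_replicated_oracle(self):
        masses = np.array([10.0, 40.0, 160.0])
        weights = np.array([3.0, 2.0, 1.0])
        replicated = np.repeat(masses, weights.astype(int))
        assert gini_biomass(masses, weights) == pytest.approx(
            gini_pairwise_oracle(replicated), abs=1e-12
        )

    def test_scale_invariance_and_upper_bound(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(1.0, 10.0, 50) + 1e-9
        assert gini_biomass(3.7 * x) == pytest.approx(gini_biomass(x), rel=1e-10)
        assert gini_biomass(x) <= 1.0 - 1.0 / len(x)

    def test_class_form_consistent_with_per_tree_form(self, grid):
        dens = np.zeros(grid.n_classes)
        dens[4:8] = [500.0, 400.0, 200.0, 50.0]
        g = gini_from_classes(grid, dens)
        keep = dens > 0
        assert g == pytest.approx(
            gini_pairwise_oracle(grid.class_masses[keep], dens[keep]), abs=1e-12
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gini_biomass(np.array([]))


class TestChiSquared:
    def test_identical_distributions_give_zero(self, grid):
        dens = np.linspace(1.0, 10.0, grid.n_classes)
        chi2, dof, p = chi_squared_classes(dens, dens, grid)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_direct_formula_on_two_cells(self, grid):
        # O=[10,20], E=[15,15] -> chi2 = 25/15 + 25/15 = 10/3
        obs = np.zeros(grid.n_classes)
        sim = np.zeros(grid.n_classes)
        obs[8], obs[9] = 10.0, 20.0
        sim[8], sim[9] = 15.0, 15.0
        chi2, dof, _ = chi_squared_classes(obs, sim, grid, m_trunc=200.0)
        assert chi2 == pytest.approx(10.0 / 3.0, rel=1e-12)
        assert dof == 1

    def test_dof_is_cells_minus_one(self, grid, allom):
        obs = np.ones(grid.n_classes)
        sim = np.ones(grid.n_classes)
        chi2, dof, _ = chi_squared_classes(obs, sim, grid, truncation_mass(7.0, allom))
        # classes with centre >= 16.69 kgC: 32..512 -> 5 cells
        assert dof == np.sum(grid.class_masses >= truncation_mass(7.0, allom)) - 1

    def test_zero_expected_cells_are_pooled(self, grid):
        obs = np.ones(grid.n_classes)
        sim = np.ones(grid.n_classes)
        sim[5] = 0.0
        with pytest.warns(UserWarning):
            chi2, dof, _ = chi_squared_classes(obs, sim, grid)
        assert dof == grid.n_classes - 2

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.uniform(1.0, 50.0, 10)
        sim = rng.uniform(1.0, 50.0, 10)
        from sprucestand import build_mass_grid

        grid = build_mass_grid()
        chi2, dof, _ = chi_squared_classes(obs, sim, grid)
        n = obs.sum()
        o = obs / obs.sum() * n
        e = sim / sim.sum() * n
        assert chi2 == pytest.approx(np.sum((o - e) ** 2 / e), rel=1e-10)
        assert dof == 9


class TestKolmogorovSmirnov:
    def test_identical_distributions(self, grid):
        dens = np.zeros(grid.n_classes)
        dens[5], dens[6] = 2.0, 1.0
        d, _ = ks_statistic(
            grid.class_masses[[5, 6]], np.array([2.0, 1.0]), grid, dens
        )
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports(self, grid):
        dens = np.zeros(grid.n_classes)
        dens[9] = 1.0
        d, _ = ks_statistic(np.array([1.0, 2.0]), 1.0, grid, dens)
        assert d == pytest.approx(1.0)

    def test_hand_checked_step_difference(self, grid):
        # obs CDF steps 0.5 at 10 and 1.0 at 20; sim steps 1.0 at 20
        dens = np.zeros(grid.n_classes)
        k20 = grid.class_of_mass(20.0)
        dens[k20] = 1.0
        obs = np.array([10.0, grid.class_masses[k20]])
        d, _ = ks_statistic(obs, 1.0, grid, dens)
        assert d == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_brute_force_sup_oracle(self, seed):
        from sprucestand import build_mass_grid

        grid = build_mass_grid()
        rng = np.random.default_rng(seed)
        masses = np.exp(rng.uniform(0.0, 6.0, 30))
        sim = rng.uniform(0.1, 1.0, grid.n_classes)
        d, _ = ks_statistic(masses, 1.0, grid, sim)
        # brute force: evaluate both CDFs on a dense mass grid
        xs = np.sort(np.concatenate([masses, grid.class_masses]))
        queries = np.unique(np.concatenate([xs, xs - 1e-7]))
        obs_cdf = np.array([(masses <= x).mean() for x in queries])
        sim_cdf = np.array(
            [sim[grid.class_masses <= x].sum() / sim.sum() for x in queries]
        )
        assert d == pytest.approx(np.max(np.abs(obs_cdf - sim_cdf)), abs=1e-6)


class TestFluxStats:
    def make(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2016-01-01", periods=n, freq="30min")
        obs = pd.Series(rng.normal(2.0, 1.0, n), index=idx)
        return obs

    def test_perfect_agreement(self):
        obs = self.make()
        stats = flux_error_stats(obs, obs)
        assert stats["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert stats["r2"] == pytest.approx(1.0)

    def test_constant_offset(self):
        obs = self.make()
        stats = flux_error_stats(obs + 1.5, obs)
        assert stats["rmse"] == pytest.approx(1.5, rel=1e-12)
        assert stats["r2"] == pytest.approx(1.0)

    def test_scaling_keeps_correlation(self):
        obs = self.make()
        stats = flux_error_stats(2.0 * obs, obs)
        assert stats["r2"] == pytest.approx(1.0)
        assert stats["rmse"] == pytest.approx(
            float(np.sqrt(np.mean(obs.to_numpy() ** 2))), rel=1e-10
        )

    def test_monthly_aggregation(self):
        idx = pd.date_range("2016-01-01", periods=120, freq="D")
        obs = pd.Series(np.arange(120.0), index=idx)
        stats = flux_error_stats(obs + 2.0, obs, cadence="monthly")
        assert stats["rmse"] == pytest.approx(2.0)
        assert stats["n"] == 4

    def test_zero_variance_r2_undefined(self):
        obs = self.make()
        flat = obs * 0.0 + 1.0
        assert np.isnan(flux_error_stats(flat, obs)["r2"])

    def test_no_overlap_rejected(self):
        obs = self.make()
        other = self.make().copy()
        other.index = other.index + pd.Timedelta(days=400)
        with pytest.raises(ValueError):
            flux_error_stats(other, obs)


class TestSeasonalDiurnalMatrix:
    def test_constant_series_gives_constant_matrix(self):
        idx = pd.date_range("2016-01-01", periods=366 * 48, freq="30min")
        m = seasonal_diurnal_matrix(pd.Series(3.0, index=idx))
        assert m.shape == (12, 48)
        assert np.allclose(m.to_numpy(), 3.0)

    def test_self_difference_is_zero(self):
        idx = pd.date_range("2016-01-01", periods=366 * 48, freq="30min")
        s = pd.Series(np.random.default_rng(0).normal(size=len(idx)), index=idx)
        m = seasonal_diurnal_matrix(s, s)
        assert np.allclose(m.to_numpy(), 0.0, atol=1e-12)

    def test_pure_diurnal_sinusoid_is_separable(self):
        idx = pd.date_range("2016-01-01", periods=366 * 48, freq="30min")
        hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
        s = pd.Series(np.sin(2 * np.pi * hour / 24.0), index=idx)
        m = seasonal_diurnal_matrix(s)
        # every month traces the same sinusoid
        assert np.allclose(m.to_numpy() - m.to_numpy()[0], 0.0, atol=1e-12)
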