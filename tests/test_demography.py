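"""Mass-class grid, stand state and the demographic step."""

import numpy as np
import pytest

from sprucestand import (
    PFTParams,
    build_mass_grid,
    canopy_cover,
    initialise_from_distribution,
    initialise_planting,
    planting_density_from_spacing,
    stand_aggregates,
    step_demography,
    truncation_mass,
)


class TestGrid:
    def test_geometric_ladder(self, grid):
        assert np.allclose(grid.class_masses, 2.0 ** np.arange(10))
        assert np.all(np.diff(grid.class_masses) > 0)
        assert np.all(grid.class_edges[:-1] < grid.class_masses)
        assert np.all(grid.class_masses < grid.class_edges[1:])

    def test_heights_strictly_increasing(self, grid):
        assert np.all(np.diff(grid.height) > 0)

    def test_truncation_mass_falls_in_class_4(self, grid, allom):
        assert grid.class_of_mass(truncation_mass(7.0, allom)) == 4

    def test_too_few_classes_rejected(self, allom, pft):
        with pytest.raises(ValueError):
            build_mass_grid(K=3, allom=allom, pft=pft)


class TestInitialisation:
    def test_planting_density_from_square_spacing(self):
        assert planting_density_from_spacing(2.0) == 2500.0

    def test_planting_puts_everything_in_seed_class(self, grid):
        state = initialise_planting(grid, 2500.0)
        assert state.number_density[0] == pytest.approx(0.25)
        assert np.all(state.number_density[1:] == 0.0)
        assert state.biomass(grid) == pytest.approx(0.25 * grid.class_masses[0])
        assert state.stand_age == 0.0

    def test_zero_density_gives_empty_stand(self, grid):
        state = initialise_planting(grid, 0.0)
        agg = stand_aggregates(state, grid)
        assert agg.n_density_ha == 0.0
        assert agg.c_density_tc_ha == 0.0
        assert agg.lai == 0.0

    def test_from_distribution_preserves_total(self, grid):
        dens = np.zeros(grid.n_classes)
        dens[3], dens[5] = 1000.0, 348.0
        state = initialise_from_distribution(grid, dens, stand_age=45.0)
        assert state.total_density() * 1e4 == pytest.approx(1348.0, rel=1e-12)

    def test_from_distribution_length_mismatch(self, grid):
        with pytest.raises(ValueError):
            initialise_from_distribution(grid, np.ones(3))


class TestCanopyCover:
    def test_empty_stand(self, grid):
        nu_total, nu_above = canopy_cover(initialise_planting(grid, 0.0), grid)
        assert nu_total == 0.0
        assert np.all(nu_above == 0.0)

    def test_cover_is_capped_at_one(self, grid):
        dens = np.full(grid.n_classes, 1.0) * 1e4  # absurdly dense
        state = initialise_from_distribution(grid, dens)
        nu_total, nu_above = canopy_cover(state, grid)
        assert nu_total == 1.0
        assert np.all(nu_above <= 1.0)

    def test_top_class_shades_all_lower_classes_equally(self, grid):
        dens = np.zeros(grid.n_classes)
        n_top = 0.4 / grid.crown_area[-1]
        dens[-1] = n_top * 1e4
        state = initialise_from_distribution(grid, dens)
        nu_total, nu_above = canopy_cover(state, grid)
        assert nu_total == pytest.approx(0.4)
        assert np.allclose(nu_above[:-1], 0.4)
        assert nu_above[-1] == 0.0  # nothing above the top class


class TestStep:
    def test_no_drivers_leaves_state_unchanged(self, grid):
        pft0 = PFTParams(gamma_base=0.0)
        state = initialise_planting(grid, 2500.0)
        out = step_demography(state, grid, pft0, npp=0.0, dt=1.0 / 12.0)
        assert np.allclose(out.number_density, state.number_density)
        assert out.litter_flux_accum == 0.0

    def test_pure_mortality_is_exponential(self, grid, pft):
        state = initialise_planting(grid, 2500.0)
        for _ in range(10):
            state = step_demography(state, grid, pft, npp=0.0, dt=1.0)
        ratio = state.total_density() / 0.25
        assert ratio == pytest.approx(np.exp(-0.1), rel=1e-12)

    def test_growth_conserves_carbon_without_mortality(self, grid):
        pft0 = PFTParams(gamma_base=0.0, alpha_repro=0.0)
        state = initialise_planting(grid, 2500.0)
        npp, dt = 0.8, 1.0 / 12.0
        before = state.biomass(grid)
        out = step_demography(state, grid, pft0, npp=npp, dt=dt)
        assert out.biomass(grid) - before == pytest.approx(npp * dt, rel=1e-10)

    def test_full_carbon_budget_closes_each_step(self, grid, pft):
        state = initialise_planting(grid, 2500.0)
        npp, dt = 0.7, 1.0 / 12.0
        for _ in range(60):
            before = state.biomass(grid) + state.litter_flux_accum
            state = step_demography(state, grid, pft, npp=npp, dt=dt)
            after = state.biomass(grid) + state.litter_flux_accum
            assert after - before == pytest.approx(npp * dt, rel=1e-8)

    def test_tree_number_budget_closes_each_step(self, grid, pft):
        state = initialise_planting(grid, 2500.0)
        dt = 1.0 / 12.0
        for _ in range(24):
            _, nu_above = canopy_cover(state, grid)
            nu_total, _ = canopy_cover(state, grid)
            n_before = state.total_density()
            deaths_expected = n_before * (1.0 - np.exp(-pft.gamma_base * dt))
            recruits_expected = (
                pft.alpha_repro * 0.9 * dt * (1.0 - nu_total) / pft.m_seed
            )
            state = step_demography(state, grid, pft, npp=0.9, dt=dt)
            delta = state.total_density() - n_before
            assert delta == pytest.approx(
                recruits_expected - deaths_expected, rel=1e-10
            )

    def test_negative_npp_touches_litter_not_structure(self, grid):
        pft0 = PFTParams(gamma_base=0.0)
        state = initialise_planting(grid, 2500.0)
        out = step_demography(state, grid, pft0, npp=-0.5, dt=1.0 / 12.0)
        assert np.allclose(out.number_density, state.number_density)
        assert out.litter_flux_accum == pytest.approx(-0.5 / 12.0)

    def test_densities_stay_non_negative_under_defaults(self, grid, pft):
        state = initialise_planting(grid, 2500.0)
        for _ in range(120):
            state = step_demography(state, grid, pft, npp=1.5, dt=0.1)
            assert np.all(state.number_density >= 0.0)

    def test_closed_canopy_suppresses_recruitment(self, grid, pft):
        dens = np.zeros(grid.n_classes)
        dens[-1] = 2.0 / grid.crown_area[-1] * 1e4  # cover = 2, capped at 1
        state = initialise_from_distribution(grid, dens)
        n_seed_before = state.number_density[0]
        out = step_demography(
            state, grid, PFTParams(gamma_base=0.0), npp=1.0, dt=1.0 / 12.0
        )
        assert out.number_density[0] == pytest.approx(n_seed_before)

    def test_oversized_timestep_rejected(self, grid, pft):
        state = initialise_planting(grid, 2500.0)
        with pytest.raises(ValueError):
            step_demography(state, grid, pft, npp=0.0, dt=2.0)


class TestAggregates:
    def test_single_class_carbon_density(self, grid):
        # 0.1348 trees m^-2 at 154.3 kgC -> 208 tC ha^-1
        dens = np.zeros(grid.n_classes)
        k = grid.class_of_mass(154.3)
        dens[k] = 0.1348 * 1e4
        state = initialise_from_distribution(grid, dens)
        carbon = 0.1348 * grid.class_masses[k] * 10.0
        agg = stand_aggregates(state, grid)
        assert agg.c_density_tc_ha == pytest.approx(carbon, rel=1e-12)
        assert agg.mean_height_m == pytest.approx(grid.height[k])

    def test_truncation_above_top_class_zeroes_structure_but_not_lai(self, grid):
        state = initialise_planting(grid, 2500.0)
        full = stand_aggregates(state, grid, m_trunc=0.0)
        cut = stand_aggregates(state, grid, m_trunc=grid.class_masses[-1] * 4)
        assert cut.n_density_ha == 0.0
        assert cut.c_density_tc_ha == 0.0
        assert cut.lai == full.lai
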