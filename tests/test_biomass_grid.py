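import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import box

from spongeimpact import (
    GridDefinition,
    SeascapeConfig,
    cell_mean_biomass,
    focal_fill,
    generate_seascape,
    sample_rv_tows,
    total_biomass,
    trawls_per_cell,
)
from spongeimpact.biomass_grid import SOURCE_FILLED, SOURCE_OBSERVED

from conftest import make_tows

ONE_CELL = GridDefinition(0.0, 0.0, 5.0, 1, 1)


class TestTrawlsPerCell:
    def test_campelen_factor(self):
        tpc = trawls_per_cell("Campelen")
        assert tpc.rounded == 373
        assert tpc.unrounded == pytest.approx(373.13, abs=0.005)

    def test_lofoten_factor(self):
        tpc = trawls_per_cell("Lofoten")
        assert tpc.rounded == 641
        assert tpc.unrounded == pytest.approx(641.03, abs=0.005)

    def test_identity_when_swept_area_equals_cell(self):
        # a gear sweeping the whole cell needs exactly one tow
        assert trawls_per_cell("Campelen", cell_area_m2=67_000).unrounded == 1.0

    def test_unknown_gear_rejected(self):
        with pytest.raises(ValueError, match="unknown gear"):
            trawls_per_cell("Agassiz")


class TestCellMeanBiomass:
    def test_single_lofoten_tow_scales_to_cell(self):
        tows = make_tows([(2.0, 2.0, "Lofoten", 100.0)])
        grid = cell_mean_biomass(tows, ONE_CELL)
        assert grid.biomass_t[0, 0] == pytest.approx(64.103, abs=5e-4)

    def test_two_campelen_tows_average_before_scaling(self):
        tows = make_tows([(1.0, 1.0, "Campelen", 50.0), (3.0, 3.0, "Campelen", 150.0)])
        grid = cell_mean_biomass(tows, ONE_CELL)
        assert grid.biomass_t[0, 0] == pytest.approx(37.313, abs=5e-4)

    def test_zero_catch_is_an_observed_zero(self):
        tows = make_tows([(2.0, 2.0, "Campelen", 0.0)])
        grid = cell_mean_biomass(tows, ONE_CELL)
        assert grid.biomass_t[0, 0] == 0.0
        assert grid.source[0, 0] == SOURCE_OBSERVED

    def test_tow_outside_extent_rejected(self, caplog):
        tows = make_tows([(2.0, 2.0, "Campelen", 10.0), (99.0, 99.0, "Campelen", 10.0)])
        with caplog.at_level("WARNING"):
            grid = cell_mean_biomass(tows, ONE_CELL)
        assert grid.n_populated == 1
        assert "outside grid extent" in caplog.text

    @given(catch=st.floats(min_value=0.0, max_value=1e5, allow_nan=False))
    def test_scaling_identity_single_tow(self, catch):
        tows = make_tows([(2.0, 2.0, "Campelen", catch)])
        grid = cell_mean_biomass(tows, ONE_CELL)
        expected = catch * trawls_per_cell("Campelen").unrounded / 1000.0
        assert grid.biomass_t[0, 0] == expected

    def test_bisected_cell_keeps_both_stratum_values(self):
        # closure over the western half; one tow per stratum
        closure = box(0.0, 0.0, 2.5, 5.0)
        tows = make_tows([(1.0, 2.0, "Lofoten", 100.0), (4.0, 2.0, "Lofoten", 10.0)])
        grid = cell_mean_biomass(tows, ONE_CELL, closures=[closure])
        v_in = 100.0 * 641.0256410 / 1000.0
        v_out = 10.0 * 641.0256410 / 1000.0
        assert grid.frac_inside[0, 0] == pytest.approx(0.5)
        assert grid.stratum_value(0, 0, "inside_closure") == pytest.approx(v_in, rel=1e-6)
        assert grid.stratum_value(0, 0, "outside_closure") == pytest.approx(v_out, rel=1e-6)
        # each half reports its own stratum's estimate
        west = total_biomass(grid, box(0.0, 0.0, 2.5, 5.0))
        east = total_biomass(grid, box(2.5, 0.0, 5.0, 5.0))
        assert west == pytest.approx(v_in / 2, rel=1e-6)
        assert east == pytest.approx(v_out / 2, rel=1e-6)
        assert grid.biomass_t[0, 0] == pytest.approx((v_in + v_out) / 2, rel=1e-6)


class TestFocalFill:
    def grid_3x3(self, cells):
        """cells: {(row, col): catch_kg} on a 15 × 15 km lattice."""
        tows = make_tows(
            [(c * 5 + 2.5, r * 5 + 2.5, "Campelen", catch) for (r, c), catch in cells.items()]
        )
        return cell_mean_biomass(tows, GridDefinition(0, 0, 5.0, 3, 3))

    def test_fill_is_mean_of_observed_neighbours(self):
        factor = trawls_per_cell("Campelen").unrounded / 1000.0
        cells = {(0, 0): 10 / factor, (0, 2): 20 / factor, (2, 2): 30 / factor}
        filled = focal_fill(self.grid_3x3(cells))
        assert filled.biomass_t[1, 1] == pytest.approx(20.0, rel=1e-9)
        assert filled.source[1, 1] == SOURCE_FILLED

    def test_cell_with_no_populated_neighbours_stays_empty(self):
        filled = focal_fill(self.grid_3x3({(0, 0): 100.0}))
        assert np.isnan(filled.biomass_t[2, 2])

    def test_fully_populated_grid_is_unchanged(self):
        grid = self.grid_3x3({(r, c): 10.0 * (r + c) for r in range(3) for c in range(3)})
        filled = focal_fill(grid)
        np.testing.assert_array_equal(filled.biomass_t, grid.biomass_t)

    def test_fill_never_alters_observed_or_loses_cells(self, tows, grid5, sea):
        grid = cell_mean_biomass(tows, grid5, [g for _, g in sea.closures])
        filled = focal_fill(grid)
        assert filled.n_populated >= grid.n_populated
        # observation is a per-stratum property: filling one stratum of a
        # bisected cell may change the merged value, never the observed layer
        for values, filled_values, src in (
            (grid.inside_t, filled.inside_t, grid.inside_source),
            (grid.outside_t, filled.outside_t, grid.outside_source),
        ):
            observed = src == SOURCE_OBSERVED
            np.testing.assert_array_equal(filled_values[observed], values[observed])

    def test_single_pass_uses_observed_values_only(self):
        # chain . X . . : the cell two steps from X must stay empty
        tows = make_tows([(2.5, 2.5, "Campelen", 100.0)])
        grid = cell_mean_biomass(tows, GridDefinition(0, 0, 5.0, 1, 4))
        filled = focal_fill(grid)
        assert not np.isnan(filled.biomass_t[0, 1])
        assert np.isnan(filled.biomass_t[0, 2])

    def test_fill_respects_stratum_boundaries(self):
        # observed inside-closure cell next to an empty outside-only cell:
        # the outside stratum has no observed neighbours, so no fill happens
        closure = box(0.0, 0.0, 5.0, 5.0)
        tows = make_tows([(2.5, 2.5, "Lofoten", 100.0)])
        grid = cell_mean_biomass(tows, GridDefinition(0, 0, 5.0, 1, 2), closures=[closure])
        filled = focal_fill(grid)
        assert np.isnan(filled.outside_t[0, 1])
        assert np.isnan(filled.biomass_t[0, 1])


class TestTotalBiomass:
    def test_all_zero_cells_total_zero(self):
        tows = make_tows([(2.5 + 5 * c, 2.5, "Campelen", 0.0) for c in range(4)])
        grid = cell_mean_biomass(tows, GridDefinition(0, 0, 5.0, 1, 4))
        assert total_biomass(grid) == 0.0

    def test_region_covering_two_of_four_cells(self):
        factor = trawls_per_cell("Campelen").unrounded / 1000.0
        tows = make_tows(
            [(2.5 + 5 * c, 2.5 + 5 * r, "Campelen", 10.0 / factor)
             for r in range(2) for c in range(2)]
        )
        grid = cell_mean_biomass(tows, GridDefinition(0, 0, 5.0, 2, 2))
        assert total_biomass(grid, box(0, 0, 10, 5)) == pytest.approx(20.0, rel=1e-9)

    def test_empty_region_warns_and_returns_zero(self):
        tows = make_tows([(2.0, 2.0, "Campelen", 10.0)])
        grid = cell_mean_biomass(tows, ONE_CELL)
        with pytest.warns(UserWarning, match="empty region"):
            assert total_biomass(grid, box(0, 0, 0, 0)) == 0.0

    def test_recovery_of_uniform_field_within_5pct(self):
        # ≥ 5 tows per cell on average over a 50 × 50 km uniform seascape
        d = 0.002
        sea = generate_seascape(
            SeascapeConfig(
                width_km=50, height_km=50, depth_min_m=100, depth_max_m=500,
                depth_relief_m=0, n_patches=0, base_density=d, n_closures=0, seed=13,
            )
        )
        tows = sample_rv_tows(sea, 1000, seed=14)
        grid = GridDefinition(0, 0, 5.0, 10, 10)
        estimate = total_biomass(focal_fill(cell_mean_biomass(tows, grid)))
        truth = sea.total_true_biomass_t()
        assert estimate == pytest.approx(truth, rel=0.05)
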