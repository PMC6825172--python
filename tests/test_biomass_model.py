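import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from spongeimpact import (
    GridDefinition,
    Raster,
    RFConfig,
    fit_and_validate,
    integrate_biomass,
    make_training_table,
    predict_surface,
)
from spongeimpact.biomass_model import RESPONSE_COLUMN

from conftest import make_tows

FAST_RF = RFConfig(n_trees=60, cv_folds=5, cv_repeats=2, seed=0)


def smooth_table(n=500, noise_sd=0.0, seed=0):
    """Response an exact smooth function of one covariate (plus a decoy)."""
    rng = np.random.default_rng(seed)
    f1 = rng.uniform(0, 1, n)
    f2 = rng.uniform(0, 1, n)  # carries no signal
    y = np.sin(2 * np.pi * f1) + 2 * f1 + rng.normal(0, noise_sd, n)
    table = pd.DataFrame({"f1": f1, "f2": f2, RESPONSE_COLUMN: y})
    table.attrs["response_mode"] = "density"
    return table


class TestMakeTrainingTable:
    def test_response_is_catch_per_swept_area(self):
        tows = make_tows([(2.0, 2.0, "Campelen", 113.9)])
        grid = GridDefinition(0, 0, 5.0, 1, 1)
        covs = {"depth": Raster(grid, np.array([[800.0]]))}
        table = make_training_table(tows, covs)
        assert table[RESPONSE_COLUMN].item() == pytest.approx(0.0017)
        assert table["depth"].item() == 800.0

    def test_zero_catch_gives_zero_response(self):
        tows = make_tows([(2.0, 2.0, "Lofoten", 0.0)])
        grid = GridDefinition(0, 0, 5.0, 1, 1)
        table = make_training_table(tows, {"depth": Raster(grid, np.array([[500.0]]))})
        assert table[RESPONSE_COLUMN].item() == 0.0

    def test_raw_catch_mode(self):
        tows = make_tows([(2.0, 2.0, "Campelen", 250.0)])
        grid = GridDefinition(0, 0, 5.0, 1, 1)
        table = make_training_table(
            tows, {"depth": Raster(grid, np.array([[500.0]]))}, response="catch"
        )
        assert table[RESPONSE_COLUMN].item() == 250.0
        assert table.attrs["response_mode"] == "catch"

    def test_tows_outside_extent_dropped(self, caplog):
        tows = make_tows([(2.0, 2.0, "Campelen", 10.0), (99.0, 2.0, "Campelen", 10.0)])
        grid = GridDefinition(0, 0, 5.0, 1, 1)
        with caplog.at_level("WARNING"):
            table = make_training_table(tows, {"depth": Raster(grid, np.array([[500.0]]))})
        assert len(table) == 1
        assert "outside the covariate extent" in caplog.text

    def test_table_shape_contract(self, sea, tows):
        table = make_training_table(tows, sea.covariates)
        assert len(table) == len(tows)
        assert not table.isna().any().any()


class TestFitAndValidate:
    def test_noiseless_smooth_response_scores_high(self):
        fitted = fit_and_validate(smooth_table(), FAST_RF)
        assert fitted.cv_r2_mean >= 0.8

    def test_pure_noise_scores_near_zero(self):
        rng = np.random.default_rng(1)
        table = smooth_table(seed=1)
        table[RESPONSE_COLUMN] = rng.normal(0, 1, len(table))
        fitted = fit_and_validate(table, FAST_RF)
        assert fitted.cv_r2_mean <= 0.1

    def test_same_seed_reproduces_scores(self):
        a = fit_and_validate(smooth_table(n=80), FAST_RF)
        b = fit_and_validate(smooth_table(n=80), FAST_RF)
        np.testing.assert_array_equal(a.cv_r2_scores, b.cv_r2_scores)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="cv_folds"):
            fit_and_validate(smooth_table(n=4), RFConfig(cv_folds=10))

    def test_report_echoes_configuration(self):
        fitted = fit_and_validate(smooth_table(n=60), FAST_RF)
        report = fitted.report()
        assert report["config"]["n_trees"] == 60
        assert report["config"]["min_node_size"] == 1  # implementation default
        assert report["n_cv_scores"] == 10


@pytest.fixture(scope="module")
def small_world():
    """A tiny grid world where density is an exact function of covariates."""
    grid = GridDefinition(0, 0, 5.0, 8, 8)
    X, Y = grid.cell_centers()
    depth = 100 + 60 * X  # reaches ~2,350 m: the deepest columns get masked
    density = 0.01 * np.exp(-(((depth - 800) / 400) ** 2))
    covs = {"depth": Raster(grid, depth), "xpos": Raster(grid, X)}
    return grid, Raster(grid, depth), covs, Raster(grid, density)


class TestPredictSurface:
    def fit_on_world(self, small_world, n=400, seed=5):
        grid, bathy, covs, dens = small_world
        rng = np.random.default_rng(seed)
        xs = rng.uniform(0, grid.width_km, n)
        ys = rng.uniform(0, grid.height_km, n)
        catch = dens.sample(xs, ys) * 67_000.0
        tows = make_tows([(x, y, "Campelen", c) for x, y, c in zip(xs, ys, catch)])
        table = make_training_table(tows, covs)
        return fit_and_validate(table, FAST_RF)

    def test_depth_mask_applied(self, small_world):
        grid, bathy, covs, dens = small_world
        fitted = self.fit_on_world(small_world)
        surface = predict_surface(fitted, covs, bathy)
        deep = bathy.values > 2000.0
        assert deep.any()
        assert np.isnan(surface.density.values[deep]).all()
        assert not np.isnan(surface.density.values[~deep]).any()

    def test_constant_zero_response_predicts_zero(self, small_world):
        grid, bathy, covs, _ = small_world
        tows = make_tows([(x * 5 + 2.5, 2.5, "Campelen", 0.0) for x in range(8)] * 2)
        table = make_training_table(tows, covs)
        fitted = fit_and_validate(table, RFConfig(n_trees=20, cv_folds=4, cv_repeats=1))
        surface = predict_surface(fitted, covs, bathy)
        assert np.nansum(surface.density.values) == 0.0

    def test_dense_training_recovers_known_total_within_15pct(self, small_world):
        grid, bathy, covs, dens = small_world
        fitted = self.fit_on_world(small_world)
        surface = predict_surface(fitted, covs, bathy)
        valid = bathy.values <= 2000.0
        truth_t = float(np.sum(dens.values[valid]) * grid.cell_area_m2 / 1000.0)
        assert surface.total_t() == pytest.approx(truth_t, rel=0.15)

    def test_misaligned_covariates_rejected(self, small_world):
        grid, bathy, covs, _ = small_world
        fitted = self.fit_on_world(small_world)
        other = GridDefinition(0, 0, 5.0, 4, 4)
        bad = {name: Raster(other, np.zeros((4, 4))) for name in covs}
        with pytest.raises(ValueError, match="aligned"):
            predict_surface(fitted, bad, bathy)

    def test_raw_catch_model_rejected_for_mapping(self, small_world):
        grid, bathy, covs, _ = small_world
        tows = make_tows([(x * 5 + 2.5, 2.5, "Campelen", 5.0) for x in range(8)] * 2)
        table = make_training_table(tows, covs, response="catch")
        fitted = fit_and_validate(table, RFConfig(n_trees=10, cv_folds=4, cv_repeats=1))
        with pytest.raises(ValueError, match="density response"):
            predict_surface(fitted, covs, bathy)

    def test_monotone_depth_mask(self, small_world):
        grid, bathy, covs, _ = small_world
        fitted = self.fit_on_world(small_world)
        wide = predict_surface(fitted, covs, bathy, depth_min_m=50, depth_max_m=2000)
        narrow = predict_surface(fitted, covs, bathy, depth_min_m=500, depth_max_m=1500)
        assert narrow.total_t() <= wide.total_t()


class TestIntegrateBiomass:
    def test_uniform_density_integrates_to_closed_form(self, uniform_surface):
        surface = uniform_surface(0.0017)  # 50 × 50 km grid
        area_m2 = surface.unmasked_area_km2() * 1e6
        assert surface.total_t() == pytest.approx(0.0017 * area_m2 / 1000.0, rel=1e-12)
        assert surface.mean_density_kg_m2() == pytest.approx(0.0017, rel=1e-12)

    def test_additive_over_disjoint_regions(self, uniform_surface):
        surface = uniform_surface(0.003)
        left = box(0, 0, 20, 50)
        right = box(20, 0, 50, 50)
        both = box(0, 0, 50, 50)
        assert integrate_biomass(surface, left) + integrate_biomass(
            surface, right
        ) == pytest.approx(integrate_biomass(surface, both), rel=1e-6)

    def test_empty_region_warns_and_returns_zero(self, uniform_surface):
        surface = uniform_surface(0.003)
        with pytest.warns(UserWarning, match="empty region"):
            assert integrate_biomass(surface, box(0, 0, 0, 0)) == 0.0
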