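import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from spongeimpact import (
    GridDefinition,
    Raster,
    generate_seascape,
    sample_rv_tows,
    simulate_vms,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sea():
    """A 200 × 200 km patchy seascape shared across read-only tests."""
    return generate_seascape(seed=7)


@pytest.fixture(scope="session")
def tows(sea):
    return sample_rv_tows(sea, n_tows=800)


@pytest.fixture(scope="session")
def pings(sea):
    return simulate_vms(sea, n_vessels=6)


@pytest.fixture(scope="session")
def grid5(sea):
    """The 5-km analysis lattice covering the seascape."""
    return GridDefinition(0.0, 0.0, 5.0, n_rows=40, n_cols=40)


def make_tows(records) -> pd.DataFrame:
    """Hand-built tow table: records of (x, y, gear, catch_kg)."""
    from spongeimpact.datasets import GEAR_SWEPT_AREA_M2

    rows = [
        (i, x, y, "T", gear, GEAR_SWEPT_AREA_M2[gear], catch)
        for i, (x, y, gear, catch) in enumerate(records)
    ]
    return pd.DataFrame(
        rows, columns=["tow_id", "x", "y", "division", "gear", "swept_area_m2", "catch_kg"]
    )


@pytest.fixture
def uniform_surface():
    """ModelSurface factory with spatially constant density (kg m⁻²)."""
    from spongeimpact.biomass_model import ModelSurface

    def build(density: float, grid: GridDefinition | None = None) -> ModelSurface:
        grid = grid or GridDefinition(0.0, 0.0, 5.0, 10, 10)
        vals = np.full(grid.shape, density)
        return ModelSurface(
            density=Raster(grid, vals), mask=np.ones(grid.shape, dtype=bool)
        )

    return build
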