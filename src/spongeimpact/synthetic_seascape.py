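"""Seeded synthetic seascapes for testing the assessment pipeline end to end.

The generator emulates the statistical structure of a bathyal sponge ground
like the Flemish Cap: a depth-graded seabed, a patchy nonnegative sponge
biomass density field (Gaussian patches with log-normal amplitudes on a
depth taper, absent beyond 2000 m), named divisions partitioning the
extent, closure polygons over the densest grounds, research-vessel tows
with 100% catchability, and vessel-track pings alternating steaming
(~9 kn) and fishing (~3 kn) phases so a 6-kn speed filter separates them
cleanly.

Everything is driven by an explicit integer seed; identical seed and
configuration reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon, box
from shapely.geometry.base import BaseGeometry

from .datasets import GEAR_SWEPT_AREA_M2, KM_PER_NM
from .rasters import GridDefinition, Raster, write_geojson

__all__ = [
    "SeascapeConfig",
    "Seascape",
    "generate_seascape",
    "sample_rv_tows",
    "simulate_vms",
    "make_catch_table",
]

TOW_COLUMNS = ["tow_id", "x", "y", "division", "gear", "swept_area_m2", "catch_kg"]
PING_COLUMNS = ["vessel_id", "timestamp", "x", "y", "speed_kn"]


@dataclass(frozen=True)
class SeascapeConfig:
    """Parameters of the synthetic world (lengths km, depths m, density kg m⁻²)."""

    width_km: float = 200.0
    height_km: float = 200.0
    resolution_km: float = 2.0
    #: seabed depth ramps west→east between these bounds, plus smooth relief
    depth_min_m: float = 100.0
    depth_max_m: float = 2600.0
    depth_relief_m: float = 150.0
    #: sponge patches: Gaussian bumps with log-normal peak amplitudes
    n_patches: int = 60
    patch_sigma_km: float = 6.0
    patch_amp_log_mean: float = -3.9  # median peak ≈ 0.02 kg m⁻²
    patch_amp_log_sd: float = 0.8
    base_density: float = 0.0002
    #: depth preference of the assemblage (taper on the patch field)
    depth_peak_m: float = 1200.0
    depth_width_m: float = 700.0
    depth_cutoff_m: float = 2000.0
    n_closures: int = 4
    #: large enough that a standard 18-nm (33-km) trawl set fits inside
    closure_radius_km: float = 20.0
    division_names: tuple[str, ...] = ("3L", "3M", "3N", "3O")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_km <= 0 or self.height_km <= 0 or self.resolution_km <= 0:
            raise ValueError("seascape dimensions and resolution must be positive")
        if self.n_patches < 0 or self.n_closures < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class Seascape:
    """A synthetic study area: rasters, polygons and the generating config."""

    config: SeascapeConfig
    grid: GridDefinition
    bathymetry: Raster  # depth in m, positive down
    covariates: dict[str, Raster]
    true_density: Raster  # sponge biomass density, kg m⁻² wet weight
    closures: list[tuple[int, BaseGeometry]]
    divisions: dict[str, BaseGeometry]

    @property
    def seed(self) -> int:
        return self.config.seed

    @property
    def extent_polygon(self) -> BaseGeometry:
        return self.grid.extent_polygon

    @property
    def closure_union(self) -> BaseGeometry:
        geoms = [g for _, g in self.closures]
        if not geoms:
            return Polygon()
        out = geoms[0]
        for g in geoms[1:]:
            out = out.union(g)
        return out

    def total_true_biomass_t(self) -> float:
        """True standing stock in tonnes (density integral; kg m⁻²·km² → t×10³)."""
        return self.true_density.integral() * 1e6 / 1e3

    def save(self, directory) -> None:
        """Write rasters (ESRI ASCII), polygons (GeoJSON) and config (YAML)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.bathymetry.write_ascii(directory / "bathymetry.asc")
        self.true_density.write_ascii(directory / "true_density.asc")
        for name, rast in self.covariates.items():
            rast.write_ascii(directory / f"covariate_{name}.asc")
        write_geojson(
            [(geom, {"code": code}) for code, geom in self.closures],
            directory / "closures.geojson",
        )
        write_geojson(
            [(geom, {"division": name}) for name, geom in self.divisions.items()],
            directory / "divisions.geojson",
        )
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self.config), fh)


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Smooth random field scaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def generate_seascape(config: SeascapeConfig | None = None, **overrides) -> Seascape:
    """Build a reproducible synthetic seascape.

    Either pass a :class:`SeascapeConfig` or keyword overrides of its fields.
    """
    if config is None:
        config = SeascapeConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    n_cols = int(round(config.width_km / config.resolution_km))
    n_rows = int(round(config.height_km / config.resolution_km))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("extent too small for the requested resolution")
    grid = GridDefinition(0.0, 0.0, config.resolution_km, n_rows, n_cols)
    X, Y = grid.cell_centers()

    # Bathymetry: west→east ramp with smooth relief, clipped positive-down.
    ramp = config.depth_min_m + (config.depth_max_m - config.depth_min_m) * (
        X / config.width_km
    )
    relief = config.depth_relief_m * (
        2.0 * _smooth_field(rng, grid.shape, sigma_cells=8.0 / config.resolution_km) - 1.0
    )
    depth = np.maximum(ramp + relief, 1.0)
    bathymetry = Raster(grid, depth)

    # Patchy density: lognormal-amplitude Gaussian bumps × depth taper.
    bumps = np.zeros(grid.shape)
    for _ in range(config.n_patches):
        cx = rng.uniform(0, config.width_km)
        cy = rng.uniform(0, config.height_km)
        amp = float(
            np.exp(rng.normal(config.patch_amp_log_mean, config.patch_amp_log_sd))
        )
        sigma = config.patch_sigma_km * rng.uniform(0.6, 1.4)
        bumps += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))
    taper = np.exp(-(((depth - config.depth_peak_m) / config.depth_width_m) ** 2))
    density = config.base_density + bumps * taper
    density[depth > config.depth_cutoff_m] = 0.0
    density = np.maximum(density, 0.0)
    true_density = Raster(grid, density)

    # Covariates: depth, slope, and two smooth environmental proxies, one of
    # which (productivity) is tied to the density field so distribution models
    # have signal to find, as the real predictor stack does.
    gy, gx = np.gradient(depth, config.resolution_km)
    slope = np.hypot(gx, gy)  # m per km
    productivity = density / (density.max() + 1e-12) + 0.1 * _smooth_field(
        rng, grid.shape, sigma_cells=6.0 / config.resolution_km
    )
    covariates = {
        "depth": Raster(grid, depth.copy()),
        "slope": Raster(grid, slope),
        "productivity": Raster(grid, productivity),
        "bottom_temp": Raster(
            grid,
            4.0
            - 2.5 * depth / config.depth_max_m
            + 0.5 * _smooth_field(rng, grid.shape, sigma_cells=10.0 / config.resolution_km),
        ),
    }

    # Divisions: vertical strips spanning the extent (cover, no overlap).
    names = config.division_names
    edges = np.linspace(0.0, config.width_km, len(names) + 1)
    divisions = {
        name: box(edges[i], 0.0, edges[i + 1], config.height_km)
        for i, name in enumerate(names)
    }

    # Closures: discs centred on the densest grounds, clipped to the extent.
    closures: list[tuple[int, BaseGeometry]] = []
    if config.n_closures > 0:
        flat = density.ravel()
        order = np.argsort(flat)[::-1]
        taken: list[Point] = []
        code = 1
        for idx in order:
            if code > config.n_closures:
                break
            r, c = divmod(idx, grid.n_cols)
            centre = Point(X[r, c], Y[r, c])
            if any(centre.distance(p) < 2.5 * config.closure_radius_km for p in taken):
                continue
            radius = config.closure_radius_km * (0.7 + 0.6 * rng.random())
            disc = centre.buffer(radius, quad_segs=24).intersection(grid.extent_polygon)
            closures.append((code, disc))
            taken.append(centre)
            code += 1

    return Seascape(
        config=config,
        grid=grid,
        bathymetry=bathymetry,
        covariates=covariates,
        true_density=true_density,
        closures=closures,
        divisions=divisions,
    )


def _division_of(seascape: Seascape, x: float, y: float) -> str | None:
    pt = Point(x, y)
    for name, geom in seascape.divisions.items():
        if geom.covers(pt):
            return name
    return None


def sample_rv_tows(
    seascape: Seascape,
    n_tows: int,
    gear_by_division: dict[str, str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw research-vessel survey tows over the seascape.

    Tow midpoints are uniform over the extent.  Each tow catches
    ``true_density(x, y) × swept_area`` kilograms — 100% catchability, the
    worst-case assumption of the assessment — with the gear (hence swept
    area, 67,000 m² Campelen / 39,000 m² Lofoten) set by the tow's division.
    """
    if n_tows < 1:
        raise ValueError("n_tows must be >= 1")
    if gear_by_division is None:
        gear_by_division = {
            name: ("Lofoten" if name == "3M" else "Campelen")
            for name in seascape.divisions
        }
    missing = set(seascape.divisions) - set(gear_by_division)
    if missing:
        raise ValueError(f"no gear mapped for divisions: {sorted(missing)}")
    for gear in gear_by_division.values():
        if gear not in GEAR_SWEPT_AREA_M2:
            raise ValueError(f"unknown gear {gear!r}")

    rng = np.random.default_rng(seascape.seed + 1 if seed is None else seed)
    xmin, ymin, xmax, ymax = seascape.grid.extent
    xs = rng.uniform(xmin, xmax, n_tows)
    ys = rng.uniform(ymin, ymax, n_tows)
    rows = []
    for i, (x, y) in enumerate(zip(xs, ys)):
        division = _division_of(seascape, x, y)
        gear = gear_by_division[division]
        swept = GEAR_SWEPT_AREA_M2[gear]
        density = float(seascape.true_density.sample(x, y))
        rows.append((i, x, y, division, gear, swept, density * swept))
    return pd.DataFrame(rows, columns=TOW_COLUMNS)


def _isobath_heading(seascape: Seascape, x: float, y: float, rng) -> float:
    """Heading (radians) along the local depth contour, random sense."""
    eps = seascape.grid.cell_size_km
    d = seascape.bathymetry.sample
    dzdx = (d(x + eps, y) - d(x - eps, y)) / (2 * eps)
    dzdy = (d(x, y + eps) - d(x, y - eps)) / (2 * eps)
    if not np.isfinite(dzdx) or not np.isfinite(dzdy) or (dzdx == 0 and dzdy == 0):
        return float(rng.uniform(0, 2 * np.pi))
    heading = np.arctan2(-dzdx, dzdy)  # perpendicular to the gradient
    if rng.random() < 0.5:
        heading += np.pi
    return float(heading)


def simulate_vms(
    seascape: Seascape,
    n_vessels: int,
    n_tows_per_vessel: int = 4,
    ping_interval_h: float = 1.0,
    fishing_leg_nm: float = 18.0,
    seed: int | None = None,
    start: str = "2010-01-01",
) -> pd.DataFrame:
    """Emit vessel-monitoring pings for a fleet trawling the seascape.

    Each vessel alternates steaming legs (9 ± 1 kn, a whole number of ping
    intervals long) with fishing legs (3 ± 0.3 kn nominal) that follow the
    local isobath, the way trawlers work a contour.  Pings fall on a regular
    clock; a ping on a fishing-leg endpoint counts as fishing, so an 18-nm
    set at 3 kn with hourly pings yields 7 fishing pings (fenceposts of 6 h).
    Recorded speeds carry small jitter but never cross the 6-kn threshold.
    """
    if ping_interval_h <= 0:
        raise ValueError("ping_interval_h must be positive")
    if n_vessels < 0 or n_tows_per_vessel < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seascape.seed + 2 if seed is None else seed)
    t0 = pd.Timestamp(start)
    xmin, ymin, xmax, ymax = seascape.grid.extent
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2

    records = []
    for vessel in range(n_vessels):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        clock = 0.0
        legs = []  # (t_start, t_end, x0, y0, heading, speed_kn, fishing)
        for _ in range(n_tows_per_vessel):
            # steaming leg: whole number of ping intervals, toward interior
            steam_h = ping_interval_h * int(rng.integers(1, 4))
            heading = np.arctan2(cy - y, cx - x) + rng.normal(0, 0.8)
            speed = float(np.clip(rng.normal(9.0, 1.0), 6.5, 14.0))
            legs.append((clock, clock + steam_h, x, y, heading, speed, False))
            x += speed * KM_PER_NM * steam_h * np.cos(heading)
            y += speed * KM_PER_NM * steam_h * np.sin(heading)
            x, y = float(np.clip(x, xmin, xmax - 1e-6)), float(np.clip(y, ymin, ymax - 1e-6))
            clock += steam_h
            # fishing leg along the isobath at a nominal 3 kn
            speed = 3.0
            fish_h = fishing_leg_nm / speed
            heading = _isobath_heading(seascape, x, y, rng)
            legs.append((clock, clock + fish_h, x, y, heading, speed, True))
            x += speed * KM_PER_NM * fish_h * np.cos(heading)
            y += speed * KM_PER_NM * fish_h * np.sin(heading)
            x, y = float(np.clip(x, xmin, xmax - 1e-6)), float(np.clip(y, ymin, ymax - 1e-6))
            clock += fish_h
        if not legs:
            continue
        n_ticks = int(np.floor(clock / ping_interval_h + 1e-9)) + 1
        for k in range(n_ticks):
            t = k * ping_interval_h
            # a tick on a fishing-leg endpoint belongs to the fishing leg
            leg = None
            for cand in legs:
                if cand[6] and cand[0] - 1e-9 <= t <= cand[1] + 1e-9:
                    leg = cand
                    break
            if leg is None:
                for cand in legs:
                    if cand[0] - 1e-9 <= t < cand[1]:
                        leg = cand
                        break
            if leg is None:
                continue
            ts, te, lx, ly, heading, speed, fishing = leg
            dist = speed * KM_PER_NM * (t - ts)
            px = float(np.clip(lx + dist * np.cos(heading), xmin, xmax - 1e-6))
            py = float(np.clip(ly + dist * np.sin(heading), ymin, ymax - 1e-6))
            if fishing:
                obs = float(np.clip(rng.normal(speed, 0.3), 0.2, 5.8))
            else:
                obs = float(np.clip(rng.normal(speed, 0.5), 6.2, 15.0))
            records.append(
                (f"V{vessel:03d}", t0 + pd.to_timedelta(t, unit="h"), px, py, obs)
            )
    df = pd.DataFrame(records, columns=PING_COLUMNS)
    if not df.empty:
        df = df.sort_values(["vessel_id", "timestamp"], kind="stable").reset_index(drop=True)
    return df


_SPECIES_POOL = [
    ("Atlantic cod", 1800.0),
    ("Atlantic redfishes", 1300.0),
    ("Greenland halibut", 3000.0),
    ("Groundfish (NS)", 1100.0),
    ("Shrimps (Pandalus borealis)", 1800.0),
    ("Mixed species (marine fish nei)", 550.0),
]


def make_catch_table(
    n_species: int = 5,
    years: tuple[int, ...] = (2010, 2011, 2012),
    seed: int = 0,
) -> pd.DataFrame:
    """Random catch-statistics table (species, year, catch_t, unit price).

    For the reported 3M figures use :func:`spongeimpact.datasets.catch_table_3m`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for species, base_price in _SPECIES_POOL[:n_species]:
        for year in years:
            catch = float(np.round(np.exp(rng.normal(8.0, 0.9))))
            price = float(np.round(base_price * rng.uniform(0.7, 1.3), 2))
            rows.append((species, year, catch, price))
    return pd.DataFrame(
        rows, columns=["species", "year", "catch_t", "unit_price_usd_per_t"]
    )
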