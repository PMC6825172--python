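"""Sponge-removal accounting: footprint × biomass overlays, simulated
trawling inside closures, and trawls-to-depletion.

Removal follows the worst-case convention of the assessment: every trawl
pass removes 100% of the sponge biomass under its swath (configurable via
``removal_rate``), so per cell the removal is the trawled area fraction
times the cell's biomass.  Both biomass surfaces are supported: the
grid-cell surface (per-stratum cells) and the model surface (per-cell
predictions).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .biomass_grid import BiomassGrid
from .biomass_model import ModelSurface
from .datasets import KM_PER_NM
from .rasters import Raster
from .vms_footprint import DEFAULT_WINGSPREAD_M, Footprint, track_to_swath

__all__ = [
    "RemovalTable",
    "SimulatedTrawlSet",
    "removal_by_cell",
    "removal_percent",
    "simulate_closure_trawls",
    "trawls_to_depletion",
]

logger = logging.getLogger(__name__)


def _cell_pieces(biomass):
    """Yield (row, col, stratum, geometry, full_cell_biomass_t, cell_area_km2).

    A *piece* is the part of a cell belonging to one stratum; its biomass
    share is the full-cell stratum value times piece area / cell area.
    """
    if isinstance(biomass, BiomassGrid):
        grid = biomass.grid
        closure = biomass.closure_union
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                v_in = biomass.inside_t[r, c]
                v_out = biomass.outside_t[r, c]
                if np.isnan(v_in) and np.isnan(v_out):
                    continue
                cell = grid.cell_polygon(r, c)
                frac = biomass.frac_inside[r, c]
                if not np.isnan(v_in) and frac > 0:
                    piece = cell.intersection(closure)
                    if not piece.is_empty:
                        yield r, c, "inside_closure", piece, float(v_in), grid.cell_area_km2
                if not np.isnan(v_out) and frac < 1:
                    piece = cell.difference(closure) if frac > 0 else cell
                    if not piece.is_empty:
                        yield r, c, "outside_closure", piece, float(v_out), grid.cell_area_km2
    elif isinstance(biomass, ModelSurface):
        grid = biomass.grid
        vals = biomass.biomass_t
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                v = vals[r, c]
                if np.isnan(v):
                    continue
                yield r, c, "modelled", grid.cell_polygon(r, c), float(v), grid.cell_area_km2
    else:
        raise TypeError(f"unsupported biomass surface type {type(biomass).__name__}")


@dataclass
class RemovalTable:
    """Per-cell removal accounting plus totals.

    ``cells`` columns: cell_row, cell_col, stratum, biomass_t (of the cell
    piece), trawled_fraction (of the piece), removal_t.
    """

    cells: pd.DataFrame
    removal_rate: float

    @property
    def total_removal_t(self) -> float:
        return float(self.cells["removal_t"].sum())

    @property
    def total_biomass_t(self) -> float:
        return float(self.cells["biomass_t"].sum())

    def regional_sums(self, regions: dict[str, BaseGeometry], biomass, footprint) -> pd.DataFrame:
        """Biomass and removal totals per named region polygon."""
        rows = []
        for name, region in regions.items():
            sub = removal_by_cell(footprint, biomass, self.removal_rate, region=region)
            rows.append((name, sub.total_biomass_t, sub.total_removal_t))
        return pd.DataFrame(rows, columns=["region", "biomass_t", "removal_t"])


def removal_by_cell(
    footprint: Footprint | BaseGeometry,
    biomass,
    removal_rate: float = 1.0,
    region: BaseGeometry | None = None,
) -> RemovalTable:
    """Overlay the footprint on a biomass surface.

    Per cell piece: removal_t = (area of piece ∩ footprint / cell area) ×
    full-cell biomass × removal_rate.  ``region`` restricts the accounting
    (both biomass and removal) to a polygon.
    """
    if not 0 <= removal_rate <= 1:
        raise ValueError("removal_rate must be within [0, 1]")
    geom = footprint.union if isinstance(footprint, Footprint) else footprint
    prepared = prep(geom) if not geom.is_empty else None
    rows = []
    for r, c, stratum, piece, full_cell_t, cell_area in _cell_pieces(biomass):
        if region is not None:
            piece = piece.intersection(region)
            if piece.is_empty:
                continue
        piece_biomass = full_cell_t * piece.area / cell_area
        if prepared is not None and prepared.intersects(piece):
            trawled_area = piece.intersection(geom).area
        else:
            trawled_area = 0.0
        removal = full_cell_t * (trawled_area / cell_area) * removal_rate
        trawled_fraction = trawled_area / piece.area if piece.area > 0 else 0.0
        rows.append((r, c, stratum, piece_biomass, trawled_fraction, removal))
    cells = pd.DataFrame(
        rows,
        columns=["cell_row", "cell_col", "stratum", "biomass_t", "trawled_fraction", "removal_t"],
    )
    return RemovalTable(cells=cells, removal_rate=removal_rate)


def removal_percent(removal_t: float, reference_biomass_t: float, ndigits: int | None = 1) -> float:
    """Removal as a percentage of an explicit reference biomass.

    The reference (e.g. biomass within the fishing footprint vs the whole
    study area) must be chosen by the caller; it changes the answer.
    """
    if reference_biomass_t <= 0:
        raise ValueError("reference biomass must be positive")
    pct = 100.0 * removal_t / reference_biomass_t
    return round(pct, ndigits) if ndigits is not None else pct


def _contour_heading(bathymetry: Raster, x: float, y: float, rng, prev: float | None = None) -> float:
    """Heading along the local isobath; keeps the sense of ``prev`` if given."""
    eps = bathymetry.grid.cell_size_km
    d = bathymetry.sample
    dzdx = float(d(x + eps, y)) - float(d(x - eps, y))
    dzdy = float(d(x, y + eps)) - float(d(x, y - eps))
    if not np.isfinite(dzdx) or not np.isfinite(dzdy) or (dzdx == 0 and dzdy == 0):
        return float(rng.uniform(0, 2 * np.pi)) if prev is None else prev
    heading = math.atan2(-dzdx, dzdy)
    if prev is None:
        if rng.random() < 0.5:
            heading += math.pi
    elif math.cos(heading - prev) < 0:
        heading += math.pi
    return heading


@dataclass
class SimulatedTrawlSet:
    """Simulated non-overlapping trawl sets inside closures, with removals."""

    trawls: pd.DataFrame  # trawl_id, closure_code, length_nm, removal_t
    paths: list[LineString] = field(repr=False)
    wingspread_m: float = DEFAULT_WINGSPREAD_M

    @property
    def n_trawls(self) -> int:
        return len(self.trawls)

    @property
    def total_removal_t(self) -> float:
        return float(self.trawls["removal_t"].sum())

    @property
    def mean_removal_t(self) -> float:
        return float(self.trawls["removal_t"].mean())

    @property
    def sd_removal_t(self) -> float:
        return float(self.trawls["removal_t"].std(ddof=1)) if self.n_trawls > 1 else 0.0


def _walk_contour(
    bathymetry: Raster,
    closure: BaseGeometry,
    start: Point,
    length_km: float,
    rng,
    step_km: float = 1.0,
    jitter_sd: float = 0.15,
) -> LineString | None:
    """Trace a contour-following path of ``length_km`` inside the closure."""
    coords = [(start.x, start.y)]
    x, y = start.x, start.y
    heading = _contour_heading(bathymetry, x, y, rng)
    walked = 0.0
    while walked < length_km - 1e-9:
        step = min(step_km, length_km - walked)
        heading = _contour_heading(bathymetry, x, y, rng, prev=heading) + rng.normal(0, jitter_sd)
        nx = x + step * math.cos(heading)
        ny = y + step * math.sin(heading)
        if not closure.covers(Point(nx, ny)):
            break
        x, y = nx, ny
        coords.append((x, y))
        walked += step
    if len(coords) < 2:
        return None
    return LineString(coords)


def simulate_closure_trawls(
    closures,
    bathymetry: Raster,
    biomass,
    n: int = 30,
    seed: int = 0,
    wingspread_m: float = DEFAULT_WINGSPREAD_M,
    default_length_nm: float = 18.0,
    small_closure_lengths_nm: tuple[float, float] = (7.0, 8.0),
    removal_rate: float = 1.0,
    max_attempts: int = 200,
) -> SimulatedTrawlSet:
    """Simulate ``n`` non-overlapping trawl sets inside the closures.

    Paths mirror a typical commercial set — ~18 nm (3 kn over 6 h) following
    the local bathymetric contour — except in the two smallest closures,
    where sets of 7 and 8 nm are used.  Trawls are allocated to closures in
    proportion to closure area, placed by rejection sampling so swaths do
    not overlap one another, and each removes ``removal_rate`` (default
    100%) of the biomass under its 100-m swath.  A path that cannot reach
    its target length inside its closure is shortened with a warning.
    """
    closures = [(code, geom) for code, geom in closures]
    if not closures:
        raise ValueError("no closures supplied")
    rng = np.random.default_rng(seed)

    lengths = {code: default_length_nm for code, _ in closures}
    if len(closures) >= 3:
        by_area = sorted(closures, key=lambda cg: cg[1].area)
        lengths[by_area[0][0]] = small_closure_lengths_nm[0]
        lengths[by_area[1][0]] = small_closure_lengths_nm[1]

    # largest-remainder allocation of n trawls by closure area
    areas = np.array([geom.area for _, geom in closures])
    quota = n * areas / areas.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n - counts.sum()]:
        counts[i] += 1

    rows = []
    paths: list[LineString] = []
    accepted_swaths: list[BaseGeometry] = []
    trawl_id = 0
    for (code, geom), count in zip(closures, counts):
        target_km = lengths[code] * KM_PER_NM
        xmin, ymin, xmax, ymax = geom.bounds
        for _ in range(count):
            best = None
            for _attempt in range(max_attempts):
                px, py = rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)
                if not geom.covers(Point(px, py)):
                    continue
                path = _walk_contour(bathymetry, geom, Point(px, py), target_km, rng)
                if path is None:
                    continue
                swath = track_to_swath(path, wingspread_m=wingspread_m)
                if any(swath.intersects(s) for s in accepted_swaths):
                    continue
                if best is None or path.length > best[0].length:
                    best = (path, swath)
                if path.length >= target_km - 1e-6:
                    break
            if best is None:
                warnings.warn(f"could not place a trawl inside closure {code}; skipped")
                continue
            path, swath = best
            if path.length < target_km - 1e-6:
                warnings.warn(
                    f"closure {code}: trawl shortened to {path.length / KM_PER_NM:.1f} nm "
                    f"of the target {lengths[code]:.0f} nm"
                )
            removal = removal_by_cell(swath, biomass, removal_rate).total_removal_t
            rows.append((trawl_id, code, path.length / KM_PER_NM, removal))
            paths.append(path)
            accepted_swaths.append(swath)
            trawl_id += 1
    trawls = pd.DataFrame(rows, columns=["trawl_id", "closure_code", "length_nm", "removal_t"])
    return SimulatedTrawlSet(trawls=trawls, paths=paths, wingspread_m=wingspread_m)


def trawls_to_depletion(total_biomass_t: float, mean_removal_per_trawl_t: float) -> int:
    """Non-overlapping trawl sets needed to remove the whole standing stock.

    Ceiling of total / mean-per-trawl: eliminating the entire stock requires
    covering the last partial trawl too.  Assumes non-overlapping sets of
    constant average yield.
    """
    if total_biomass_t < 0:
        raise ValueError("total biomass must be nonnegative")
    if total_biomass_t == 0:
        return 0
    if mean_removal_per_trawl_t <= 0:
        raise ValueError("mean removal per trawl must be positive")
    return math.ceil(total_biomass_t / mean_removal_per_trawl_t)
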