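"""Planar grids, rasters and lightweight vector I/O.

All spatial data in this package live in a planar, equal-area coordinate
system with kilometre units: x increases eastward, y northward.  Areas are
km², densities kg m⁻², biomass tonnes wet weight.  Rasters are serialized
as ESRI ASCII grids (plain text), vector layers as GeoJSON with the same
planar coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridDefinition",
    "Raster",
    "read_ascii_grid",
    "read_geojson",
    "write_geojson",
]


@dataclass(frozen=True)
class GridDefinition:
    """An axis-aligned lattice of square cells.

    Cells are indexed row-major from the origin (row 0 at the southern
    edge, column 0 at the western edge).  Cell membership uses half-open
    intervals [x0, x0 + cell) so a point on a shared edge belongs to
    exactly one cell.
    """

    x0: float
    y0: float
    cell_size_km: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0 or self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions and cell size must be positive")

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def cell_area_m2(self) -> float:
        return self.cell_area_km2 * 1e6

    @property
    def width_km(self) -> float:
        return self.n_cols * self.cell_size_km

    @property
    def height_km(self) -> float:
        return self.n_rows * self.cell_size_km

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        return (self.x0, self.y0, self.x0 + self.width_km, self.y0 + self.height_km)

    @property
    def extent_polygon(self) -> BaseGeometry:
        return box(*self.extent)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return (xmin <= x < xmax) and (ymin <= y < ymax)

    def cell_index(self, x, y):
        """(row, col) of the cell holding each point; vectorized."""
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size_km).astype(int)
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size_km).astype(int)
        return row, col

    def cell_polygon(self, row: int, col: int) -> BaseGeometry:
        s = self.cell_size_km
        x = self.x0 + col * s
        y = self.y0 + row * s
        return box(x, y, x + s, y + s)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-center coordinates, shape (n_rows, n_cols)."""
        s = self.cell_size_km
        xs = self.x0 + s * (np.arange(self.n_cols) + 0.5)
        ys = self.y0 + s * (np.arange(self.n_rows) + 0.5)
        return np.meshgrid(xs, ys)


@dataclass
class Raster:
    """A single-band raster on a :class:`GridDefinition`.

    ``values[row, col]``; NaN marks no-data.
    """

    grid: GridDefinition
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def sample(self, x, y):
        """Value of the cell containing each point (NaN outside the extent)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        row, col = self.grid.cell_index(x, y)
        inside = (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        out = np.full(np.shape(x), np.nan)
        out[inside] = self.values[row[inside], col[inside]]
        return out if out.ndim else float(out)

    def integral(self) -> float:
        """Sum of value × cell area over non-NaN cells (units: value·km²)."""
        return float(np.nansum(self.values) * self.grid.cell_area_km2)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy())

    def write_ascii(self, path, nodata: float = -9999.0) -> None:
        """Write as an ESRI ASCII grid (rows top-down, as the format requires)."""
        vals = np.where(np.isnan(self.values), nodata, self.values)
        header = (
            f"ncols {self.grid.n_cols}\n"
            f"nrows {self.grid.n_rows}\n"
            f"xllcorner {self.grid.x0}\n"
            f"yllcorner {self.grid.y0}\n"
            f"cellsize {self.grid.cell_size_km}\n"
            f"NODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals[vals == nodata] = np.nan
    grid = GridDefinition(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size_km=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
    )
    return Raster(grid, vals)


def write_geojson(features, path) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": dict(props)}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_geojson(path) -> list[tuple[BaseGeometry, dict]]:
    """Read a GeoJSON FeatureCollection into (geometry, properties) pairs."""
    with open(path) as fh:
        collection = json.load(fh)
    return [
        (shape(feat["geometry"]), feat.get("properties") or {})
        for feat in collection["features"]
    ]
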