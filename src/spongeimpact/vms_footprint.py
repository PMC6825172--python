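"""Trawl-track reconstruction from VMS pings and the swept-area footprint.

Pings slower than 6 knots are taken as fishing; runs of two or more
consecutive fishing pings from one vessel become a trawl track; each track
is buffered to a 100-m-wide swath (the assumed commercial wingspread) and
the union of swaths is the footprint — seabed trawled at least once,
ignoring repeat passes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon
from shapely.geometry.base import BaseGeometry

from .rasters import write_geojson

__all__ = [
    "TrawlTrack",
    "Footprint",
    "FISHING_SPEED_MAX_KN",
    "DEFAULT_WINGSPREAD_M",
    "filter_fishing_pings",
    "build_tracks",
    "track_to_swath",
    "union_footprint",
    "coverage_fraction",
]

logger = logging.getLogger(__name__)

FISHING_SPEED_MAX_KN = 6.0
DEFAULT_WINGSPREAD_M = 100.0


@dataclass
class TrawlTrack:
    """A polyline of consecutive fishing pings from one vessel."""

    vessel_id: str
    line: LineString
    timestamps: list = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.line.coords) < 2:
            raise ValueError("a trawl track needs at least 2 vertices")

    @property
    def length_km(self) -> float:
        return self.line.length

    @property
    def n_pings(self) -> int:
        return len(self.line.coords)


@dataclass
class Footprint:
    """Per-track swaths and their union ("trawled at least once")."""

    swaths: list[BaseGeometry]
    union: BaseGeometry
    region: BaseGeometry | None = None

    @property
    def area_km2(self) -> float:
        return self.union.area

    @property
    def n_tracks(self) -> int:
        return len(self.swaths)

    def write_geojson(self, path) -> None:
        write_geojson([(self.union, {"area_km2": self.area_km2})], path)


def filter_fishing_pings(pings: pd.DataFrame, speed_max_kn: float = FISHING_SPEED_MAX_KN) -> pd.DataFrame:
    """Pings with speed strictly below the fishing threshold, order preserved.

    A ping at exactly the threshold counts as steaming.
    """
    return pings[pings["speed_kn"] < speed_max_kn]


def _infer_ping_interval(times: np.ndarray):
    """Nominal ping cadence: the smallest positive inter-ping interval."""
    if len(times) < 2:
        return None
    diffs = np.diff(times)
    positive = diffs[diffs > type(diffs[0])(0)]
    return positive.min() if len(positive) else None


def build_tracks(fishing_pings: pd.DataFrame, max_gap=None) -> list[TrawlTrack]:
    """Maximal runs of ≥ 2 consecutive fishing pings, one polyline per run.

    A run breaks at a vessel change or at a temporal gap.  With an explicit
    ``max_gap``, a run breaks when the time since the previous ping strictly
    exceeds it.  By default the nominal ping cadence is inferred per vessel
    (smallest positive inter-ping interval) and a run breaks once the gap
    reaches twice that cadence — i.e. whenever at least one intervening
    ping (such as an excluded steaming ping) is missing from the run.
    Input is sorted by vessel and time internally, with a warning if it was
    not already.
    """
    if fishing_pings.empty:
        return []
    df = fishing_pings
    sorted_df = df.sort_values(["vessel_id", "timestamp"], kind="stable")
    if not sorted_df.index.equals(df.index):
        warnings.warn("pings were not sorted by vessel and time; sorting internally")
    tracks: list[TrawlTrack] = []
    for vessel_id, group in sorted_df.groupby("vessel_id", sort=False):
        times = group["timestamp"].to_numpy()
        if max_gap is not None:
            gap, inclusive = max_gap, False
        else:
            interval = _infer_ping_interval(times)
            gap, inclusive = (2 * interval, True) if interval is not None else (None, False)
        runs: list[list[int]] = [[0]]
        for i in range(1, len(group)):
            dt = times[i] - times[i - 1]
            broken = gap is not None and (dt >= gap if inclusive else dt > gap)
            if broken:
                runs.append([i])
            else:
                runs[-1].append(i)
        xs = group["x"].to_numpy()
        ys = group["y"].to_numpy()
        for run in runs:
            if len(run) < 2:
                continue
            coords = [(xs[i], ys[i]) for i in run]
            line = LineString(coords)
            if line.length == 0:
                logger.warning("degenerate zero-length track for %s skipped", vessel_id)
                continue
            tracks.append(
                TrawlTrack(vessel_id=str(vessel_id), line=line, timestamps=list(times[run]))
            )
    return tracks


def track_to_swath(
    track: TrawlTrack | LineString,
    wingspread_m: float = DEFAULT_WINGSPREAD_M,
    flat_caps: bool = True,
) -> BaseGeometry:
    """Buffer a track to its trawled swath polygon.

    The polyline is buffered by half the wingspread on each side with flat
    end caps, so a straight track of length L sweeps exactly L × wingspread.
    Rounded caps are available via ``flat_caps=False``.
    """
    if wingspread_m <= 0:
        raise ValueError("wingspread must be positive")
    line = track.line if isinstance(track, TrawlTrack) else track
    if line.length == 0:
        raise ValueError("cannot buffer a zero-length track")
    half_width_km = wingspread_m / 2 / 1000.0
    return line.buffer(half_width_km, cap_style="flat" if flat_caps else "round")


def union_footprint(swaths, region: BaseGeometry | None = None) -> Footprint:
    """Union the swaths (clipped to ``region`` if given) into a footprint."""
    swaths = list(swaths)
    union: BaseGeometry = Polygon()
    for swath in swaths:
        union = union.union(swath)
    if region is not None:
        union = union.intersection(region)
    return Footprint(swaths=swaths, union=union, region=region)


def coverage_fraction(footprint_area_km2: float, region_area_km2: float, ndigits: int | None = 1) -> float:
    """Footprint area as a percentage of the region area."""
    if region_area_km2 <= 0:
        raise ValueError("region area must be positive")
    pct = 100.0 * footprint_area_km2 / region_area_km2
    return round(pct, ndigits) if ndigits is not None else pct


def tracks_to_geojson(tracks: list[TrawlTrack], path) -> None:
    """Write tracks as a GeoJSON LineString layer."""
    write_geojson(
        [
            (t.line, {"vessel_id": t.vessel_id, "length_km": t.length_km, "n_pings": t.n_pings})
            for t in tracks
        ],
        path,
    )
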