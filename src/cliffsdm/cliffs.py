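"""Coastal cliff delineation from a terrain model, and distance predictors.

Shore-perpendicular transects are cast every few meters along a coastline
baseline.  Along each transect an elevation profile is sampled from the DTM
and scanned for a cliff: the *Toe* (seaward base) is the first sample rising
above a minimal elevation, the *Top* is the end of the contiguous steep
ascending run that follows.  A Toe/Top pair qualifies as a cliff when the
overall slope of the segment is at least 70% and the Top sits at 15 m of
altitude or more.  The retained Top points are rasterized into the
distance-to-cliffs predictor (minimum Euclidean distance from each cell
center to any Top point).

The Top/Toe scan (ascending-run with a 30% per-step slope and a 1 m toe
elevation, both configurable) is this package's concrete delineation rule;
manual curation of Top points is supported through include/exclude id lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import shapely
from shapely.geometry import LineString, Point

from .grids import Grid, haversine_m

__all__ = [
    "Transect",
    "TransectProfile",
    "CliffPoint",
    "build_transects",
    "extract_profile",
    "detect_top_toe",
    "delineate_cliffs",
    "distance_raster",
    "shore_distance_raster",
    "cliff_points_to_geojson",
    "read_coastline_geojson",
    "write_coastline_geojson",
]


@dataclass
class Transect:
    id: int
    anchor: tuple[float, float]       # point on the baseline
    direction: tuple[float, float]    # unit vector, pointing inland
    length_m: float
    step_m: float

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.direction))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("transect direction must be a unit vector")
        if self.length_m <= 0 or self.step_m <= 0:
            raise ValueError("transect length and step must be > 0")


@dataclass
class TransectProfile:
    """Ordered samples along one transect."""

    transect_id: int
    distance_m: np.ndarray    # along-transect distance, strictly increasing
    elevation_m: np.ndarray
    shore_distance_m: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.distance_m) and np.any(np.diff(self.distance_m) <= 0):
            raise ValueError("profile distances must be strictly increasing")
        if len(self.elevation_m) and not np.all(np.isfinite(self.elevation_m)):
            raise ValueError("profile elevations must be finite")


@dataclass
class CliffPoint:
    x: float
    y: float
    role: str                 # "Top" | "Toe"
    elevation_m: float
    pair_id: int              # transect id linking the Top/Toe pair
    slope_pct: float          # overall slope of the Top-Toe segment

    def __post_init__(self) -> None:
        if self.role not in ("Top", "Toe"):
            raise ValueError("role must be 'Top' or 'Toe'")


# ---------------------------------------------------------------------------
# Transect construction
# ---------------------------------------------------------------------------

def _vertex_tangents(coords: np.ndarray, smooth_window: int) -> np.ndarray:
    """Per-vertex unit tangents, moving-average smoothed over the window."""
    n = len(coords)
    t = np.empty_like(coords)
    t[1:-1] = coords[2:] - coords[:-2]
    t[0] = coords[1] - coords[0]
    t[-1] = coords[-1] - coords[-2]
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    if smooth_window > 1:
        w = smooth_window
        sm = np.empty_like(t)
        for i in range(n):
            lo, hi = max(0, i - w // 2), min(n, i + w // 2 + 1)
            sm[i] = t[lo:hi].mean(axis=0)
        sm /= np.linalg.norm(sm, axis=1, keepdims=True)
        t = sm
    return t


def build_transects(
    coastline: LineString | np.ndarray,
    spacing_m: float = 5.0,
    length_m: float = 300.0,
    step_m: float = 2.0,
    smooth_window: int = 3,
    land_side: str = "left",
) -> list[Transect]:
    """Cast shore-perpendicular transects along the coastline baseline.

    Anchors are placed every ``spacing_m`` meters of arc length (count =
    floor(arclength / spacing) + 1).  Directions are perpendicular to the
    locally smoothed tangent and point inland; by convention land lies to the
    ``land_side`` of the baseline's direction of travel.
    """
    if spacing_m <= 0 or length_m <= 0 or step_m <= 0:
        raise ValueError("spacing, length and step must be > 0")
    line = coastline if isinstance(coastline, LineString) else LineString(np.asarray(coastline))
    if len(line.coords) < 2 or line.length == 0:
        raise ValueError("degenerate coastline: need >= 2 distinct vertices")
    if land_side not in ("left", "right"):
        raise ValueError("land_side must be 'left' or 'right'")

    coords = np.asarray(line.coords, dtype=float)
    seg_len = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    tangents = _vertex_tangents(coords, smooth_window)

    n_anchors = int(np.floor(line.length / spacing_m)) + 1
    transects: list[Transect] = []
    for i in range(n_anchors):
        s = min(i * spacing_m, line.length)
        p = line.interpolate(s)
        j = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg_len) - 1)
        frac = 0.0 if seg_len[j] == 0 else (s - cum[j]) / seg_len[j]
        t = (1 - frac) * tangents[j] + frac * tangents[j + 1]
        t /= np.hypot(*t)
        normal = np.array([-t[1], t[0]]) if land_side == "left" else np.array([t[1], -t[0]])
        transects.append(Transect(
            id=i, anchor=(p.x, p.y), direction=(float(normal[0]), float(normal[1])),
            length_m=length_m, step_m=step_m,
        ))
    return transects


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def extract_profile(dtm: Grid, transect: Transect,
                    coastline: LineString | None = None) -> TransectProfile:
    """Sample the DTM along the transect every ``step_m`` meters (bilinear)."""
    n = int(np.floor(transect.length_m / transect.step_m)) + 1
    d = transect.step_m * np.arange(n)
    ax, ay = transect.anchor
    ux, uy = transect.direction
    xs = ax + d * ux
    ys = ay + d * uy

    nrows, ncols = dtm.shape
    xmin, xmax = dtm.x_origin, dtm.x_origin + ncols * dtm.cell_size
    ymin, ymax = dtm.y_origin - nrows * dtm.cell_size, dtm.y_origin
    inside = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
    if not inside.any():
        raise ValueError(f"transect {transect.id} lies entirely outside the DTM extent")
    d, xs, ys = d[inside], xs[inside], ys[inside]

    elev = dtm.sample_bilinear(xs, ys)
    if coastline is not None:
        shore = shapely.distance(shapely.points(xs, ys), coastline)
    else:
        shore = d.copy()
    return TransectProfile(transect_id=transect.id, distance_m=d,
                           elevation_m=elev, shore_distance_m=np.asarray(shore),
                           x=xs, y=ys)


def detect_top_toe(
    profile: TransectProfile,
    slope_min_pct: float = 70.0,
    top_min_elev_m: float = 15.0,
    seg_slope_pct: float = 30.0,
    toe_min_elev_m: float = 1.0,
) -> tuple[CliffPoint, CliffPoint] | None:
    """Scan the profile inland for a Top/Toe cliff pair.

    Walking inland, the Toe is the first sample above ``toe_min_elev_m``; the
    candidate run is the maximal contiguous ascending run from the Toe whose
    per-step slope is at least ``seg_slope_pct``; the Top is that run's last
    sample.  The pair qualifies iff the overall Top–Toe slope is at least
    ``slope_min_pct`` and the Top elevation is at least ``top_min_elev_m``.
    Absence of a cliff is a valid result (returns None).
    """
    z = profile.elevation_m
    d = profile.distance_m
    if len(z) == 0:
        raise ValueError("empty profile")
    above = np.flatnonzero(z > toe_min_elev_m)
    if above.size == 0:
        return None
    i_toe = int(above[0])
    i = i_toe
    while i + 1 < len(z):
        dz, dd = z[i + 1] - z[i], d[i + 1] - d[i]
        if dz <= 0 or 100.0 * dz / dd < seg_slope_pct:
            break
        i += 1
    i_top = i
    if i_top == i_toe:
        return None
    slope = 100.0 * (z[i_top] - z[i_toe]) / (d[i_top] - d[i_toe])
    if slope < slope_min_pct or z[i_top] < top_min_elev_m:
        return None
    top = CliffPoint(float(profile.x[i_top]), float(profile.y[i_top]), "Top",
                     float(z[i_top]), profile.transect_id, float(slope))
    toe = CliffPoint(float(profile.x[i_toe]), float(profile.y[i_toe]), "Toe",
                     float(z[i_toe]), profile.transect_id, float(slope))
    return top, toe


def delineate_cliffs(
    dtm: Grid,
    coastline: LineString | np.ndarray,
    spacing_m: float = 5.0,
    length_m: float = 300.0,
    step_m: float = 2.0,
    slope_min_pct: float = 70.0,
    top_min_elev_m: float = 15.0,
    seg_slope_pct: float = 30.0,
    toe_min_elev_m: float = 1.0,
    smooth_window: int = 3,
    land_side: str = "left",
    include_ids: tuple[int, ...] = (),
    exclude_ids: tuple[int, ...] = (),
) -> list[CliffPoint]:
    """Full delineation: transects -> profiles -> Top/Toe pairs.

    ``include_ids``/``exclude_ids`` stand in for the manual curation of Top
    points: excluded transect ids are dropped even if a cliff was detected;
    include ids only filter (a transect with no detected pair cannot be
    forced).  Returns the flat list of Top and Toe points.
    """
    line = coastline if isinstance(coastline, LineString) else LineString(np.asarray(coastline))
    transects = build_transects(line, spacing_m, length_m, step_m,
                                smooth_window, land_side)
    points: list[CliffPoint] = []
    for t in transects:
        if t.id in exclude_ids:
            continue
        if include_ids and t.id not in include_ids:
            continue
        try:
            profile = extract_profile(dtm, t, line)
        except ValueError:
            continue  # transect off the DTM: no information
        pair = detect_top_toe(profile, slope_min_pct, top_min_elev_m,
                              seg_slope_pct, toe_min_elev_m)
        if pair is not None:
            points.extend(pair)
    return points


# ---------------------------------------------------------------------------
# Distance rasters
# ---------------------------------------------------------------------------

def distance_raster(template: Grid, points: list[CliffPoint] | np.ndarray,
                    role: str = "Top", lonlat: bool = False,
                    name: str = "dist_cliffs") -> Grid:
    """Per-cell minimum distance (m) from the cell center to any Top point.

    Vectorized min over the point set using the same scalar expression a
    brute-force double loop would use, so the two agree exactly.
    """
    if isinstance(points, np.ndarray):
        pts = points.reshape(-1, 2).astype(float)
    else:
        pts = np.array([[p.x, p.y] for p in points if p.role == role], dtype=float)
    if len(pts) == 0:
        raise ValueError("empty point set")
    cx, cy = template.cell_centers()
    if lonlat:
        dmin = np.full(template.shape, np.inf)
        for px, py in pts:
            dmin = np.minimum(dmin, haversine_m(cx, cy, px, py))
    else:
        dmin = np.full(template.shape, np.inf)
        for px, py in pts:
            dx = cx - px
            dy = cy - py
            dmin = np.minimum(dmin, (dx * dx + dy * dy) ** 0.5)
    return Grid(values=dmin, x_origin=template.x_origin, y_origin=template.y_origin,
                cell_size=template.cell_size, nodata=template.nodata, name=name)


def shore_distance_raster(template: Grid, coastline: LineString | np.ndarray,
                          name: str = "shore_distance") -> Grid:
    """Per-cell distance (m) from the cell center to the coastline polyline."""
    line = coastline if isinstance(coastline, LineString) else LineString(np.asarray(coastline))
    cx, cy = template.cell_centers()
    d = shapely.distance(shapely.points(cx.ravel(), cy.ravel()), line)
    return Grid(values=np.asarray(d).reshape(template.shape),
                x_origin=template.x_origin, y_origin=template.y_origin,
                cell_size=template.cell_size, nodata=template.nodata, name=name)


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def cliff_points_to_geojson(points: list[CliffPoint], path: str | Path) -> Path:
    features = [{
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
        "properties": {"role": p.role, "elevation_m": p.elevation_m,
                       "pair_id": p.pair_id, "slope_pct": p.slope_pct},
    } for p in points]
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def write_coastline_geojson(coastline: LineString, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "type": "Feature",
        "geometry": shapely.geometry.mapping(coastline),
        "properties": {"kind": "coastline"},
    }))
    return path


def read_coastline_geojson(path: str | Path) -> LineString:
    data = json.loads(Path(path).read_text())
    geom = data["geometry"] if data.get("type") == "Feature" else data
    return shapely.geometry.shape(geom)
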