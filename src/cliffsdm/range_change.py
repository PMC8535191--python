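"""Binary range maps, dispersal limitation, change accounting and land use.

Suitability maps are binarized at the 10-percentile training presence
threshold (suitable at or above the threshold).  A present and a future
binary map are compared cell-by-cell into maintained (1→1), lost (1→0) and
gained (0→1) categories, optionally after masking both maps with the
dispersal-limitation polygon — the minimum convex polygon of the presences
buffered by 2 km and cropped to at most 7 km from the shoreline, the area
beyond which a poor disperser cannot establish.  Net gain is
100·(future − current)/current within the accounting domain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, mapping

from .grids import CategoricalGrid, Grid, LANDUSE_CLASSES, align_check

__all__ = [
    "BinaryMap",
    "DispersalPolygon",
    "ChangeSummary",
    "binarize",
    "count_above",
    "build_dispersal_polygon",
    "change_account",
    "landuse_crosstab",
]


@dataclass
class BinaryMap:
    """Presence/absence grid with the threshold and scenario that produced it."""

    grid: Grid
    threshold: float
    scenario: str = ""

    def __post_init__(self) -> None:
        vals = self.grid.valid_values()
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("binary map must contain only 0/1 outside nodata")

    def presence_count(self) -> int:
        return int(self.grid.valid_values().sum())

    def masked(self, mask: np.ndarray) -> "BinaryMap":
        """Zero out presence cells outside the mask (nodata propagates)."""
        v = self.grid.values.copy()
        valid = self.grid.valid_mask()
        v[valid & ~mask] = 0.0
        return BinaryMap(self.grid.with_values(v), self.threshold, self.scenario)


@dataclass
class DispersalPolygon:
    """Buffered convex hull of the presences, cropped by shore distance."""

    polygon: shapely.Polygon
    buffer_m: float
    max_shore_m: float
    cell_mask: np.ndarray          # True where cells are inside the constraint

    def to_geojson(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "type": "Feature", "geometry": mapping(self.polygon),
            "properties": {"buffer_m": self.buffer_m, "max_shore_m": self.max_shore_m},
        }))
        return path


@dataclass
class ChangeSummary:
    scenario: str
    maintained: int
    lost: int
    gained: int
    constrained: bool

    def __post_init__(self) -> None:
        # accounting identities are structural; violation means a logic bug
        assert self.maintained + self.lost == self.current
        assert self.maintained + self.gained == self.future

    @property
    def current(self) -> int:
        return self.maintained + self.lost

    @property
    def future(self) -> int:
        return self.maintained + self.gained

    @property
    def net_gain_pct(self) -> float:
        if self.current == 0:
            return float("nan")
        return round(100.0 * (self.future - self.current) / self.current, 1)

    def as_row(self) -> dict:
        return {"scenario": self.scenario, "constrained": self.constrained,
                "current": self.current, "future": self.future,
                "maintained": self.maintained, "lost": self.lost,
                "gained": self.gained, "net_gain_pct": self.net_gain_pct}


def binarize(suitability: Grid, threshold: float, scenario: str = "") -> BinaryMap:
    """Suitable (1) at or above the threshold; nodata propagates."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    v = suitability.values
    out = np.where(v == suitability.nodata, suitability.nodata,
                   (v >= threshold).astype(float))
    return BinaryMap(suitability.with_values(out, name="binary"), threshold, scenario)


def count_above(suitability: Grid, cut: float = 0.60) -> int:
    """Number of valid cells with suitability strictly above the cut."""
    return int(np.sum(suitability.valid_values() > cut))


def build_dispersal_polygon(
    presence_coords: np.ndarray,
    shore_distance: Grid,
    buffer_m: float = 2000.0,
    max_shore_m: float = 7000.0,
) -> DispersalPolygon:
    """MCP of the presences + outward buffer, cropped by shore distance.

    The cell mask marks cells whose centers fall inside (or on the boundary
    of) the buffered hull AND whose shore distance does not exceed
    ``max_shore_m``.
    """
    pts = np.asarray(presence_coords, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 presence points for a convex polygon")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("presence points are collinear; convex hull is degenerate")
    poly = hull.buffer(buffer_m) if buffer_m > 0 else hull
    cx, cy = shore_distance.cell_centers()
    inside = shapely.covers(poly, shapely.points(cx.ravel(), cy.ravel()))
    mask = inside.reshape(shore_distance.shape)
    mask &= shore_distance.valid_mask() & (shore_distance.values <= max_shore_m)
    return DispersalPolygon(polygon=poly, buffer_m=buffer_m,
                            max_shore_m=max_shore_m, cell_mask=mask)


def change_account(
    current: BinaryMap,
    future: BinaryMap,
    constraint: DispersalPolygon | None = None,
) -> tuple[ChangeSummary, Grid]:
    """Maintained/lost/gained accounting plus the categorical change map.

    With a dispersal constraint both maps are masked first, so cells outside
    the polygon count as absences in either period.  The change map codes:
    0 absent, 1 maintained, 2 lost, 3 gained.
    """
    if not align_check([current.grid, future.grid]):
        raise ValueError("current and future maps are not aligned")
    if constraint is not None:
        current = current.masked(constraint.cell_mask)
        future = future.masked(constraint.cell_mask)
    cur = current.grid.values
    fut = future.grid.values
    valid = current.grid.valid_mask() & future.grid.valid_mask()
    maintained = int(np.sum((cur == 1) & (fut == 1) & valid))
    lost = int(np.sum((cur == 1) & (fut == 0) & valid))
    gained = int(np.sum((cur == 0) & (fut == 1) & valid))
    summary = ChangeSummary(scenario=future.scenario, maintained=maintained,
                            lost=lost, gained=gained,
                            constrained=constraint is not None)
    codes = np.full(cur.shape, current.grid.nodata)
    codes[valid] = 0.0
    codes[valid & (cur == 1) & (fut == 1)] = 1.0
    codes[valid & (cur == 1) & (fut == 0)] = 2.0
    codes[valid & (cur == 0) & (fut == 1)] = 3.0
    change_map = current.grid.with_values(codes, name=f"change_{future.scenario}")
    return summary, change_map


def landuse_crosstab(prediction: BinaryMap, landuse: CategoricalGrid) -> pd.Series:
    """Percent of predicted presence cells in each land-use class.

    Returns a Series over the five classes summing to 100 (within rounding);
    an empty prediction yields an all-zero row flagged ``extinct``.  Presence
    cells with nodata land use are tallied in an ``unclassified`` audit entry
    excluded from the percentages.
    """
    if not align_check([prediction.grid, landuse]):
        raise ValueError("prediction and land-use grids are not aligned")
    legend_names = set(landuse.legend.values())
    if legend_names != set(LANDUSE_CLASSES):
        raise ValueError(f"land-use legend must be the classes {LANDUSE_CLASSES}")
    pres = (prediction.grid.values == 1) & prediction.grid.valid_mask()
    lu_valid = landuse.valid_mask()
    unclassified = int(np.sum(pres & ~lu_valid))
    if unclassified:
        warnings.warn(f"{unclassified} presence cells have no land-use class",
                      stacklevel=2)
    counted = pres & lu_valid
    total = int(counted.sum())
    out = {name: 0.0 for name in LANDUSE_CLASSES}
    if total == 0:
        out["extinct"] = True
    else:
        for code, name in landuse.legend.items():
            out[name] = 100.0 * int(np.sum(counted & (landuse.values == code))) / total
        out["extinct"] = False
    out["unclassified_cells"] = unclassified
    return pd.Series(out)
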