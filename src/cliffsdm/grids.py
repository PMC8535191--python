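"""Georeferenced single-band rasters and their plain-text I/O.

The :class:`Grid` is the universal carrier for every raster in the pipeline:
predictors, terrain, suitability surfaces and masks.  Synthetic worlds live in
a planar metric CRS (meters); real lon/lat rasters are accepted, in which case
downstream distance computations switch to the haversine great-circle formula.

Raster files use the ESRI ASCII grid format, a header of six ``key value``
lines followed by whitespace-separated rows.  It is text, diff-able, and
round-trips bit-exactly for the printed precision — which is why it is the
reference format for tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Grid",
    "CategoricalGrid",
    "ScenarioStack",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "align_check",
    "alignment_report",
    "LANDUSE_CLASSES",
]

#: The five land-use classes of the reclassified land-cover grid.
LANDUSE_CLASSES = ("Water", "Forest", "Scrubland", "Cropland", "Urban")

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised when an ASCII grid file is malformed; names the offending field."""


@dataclass
class Grid:
    """A single-band raster.

    Parameters
    ----------
    values
        2-D array; row 0 is the northernmost row.
    x_origin, y_origin
        Map coordinates of the *upper-left corner* of the upper-left cell.
    cell_size
        Positive cell edge length in map units (meters for synthetic data).
    nodata
        Sentinel for missing cells; never enters statistics.
    name
        Variable label (e.g. ``"bio9"`` or ``"dist_cliffs"``).
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = DEFAULT_NODATA
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a 2-D array with both dims >= 1")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        v = self.values[self.values != self.nodata]
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("non-nodata grid values must be finite")

    # -- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.size

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, same shape as values."""
        nrows, ncols = self.shape
        cs = self.cell_size
        xs = self.x_origin + cs * (np.arange(ncols) + 0.5)
        ys = self.y_origin - cs * (np.arange(nrows) + 0.5)
        return np.meshgrid(xs, ys)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y).

        Cell extents are half-open: ``[x, x+cs) x (y-cs, y]`` so each point
        belongs to exactly one cell.
        """
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - y) / self.cell_size))
        # top edge belongs to the first row
        if y == self.y_origin:
            row = 0
        nrows, ncols = self.shape
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise IndexError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def sample_bilinear(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at map coordinates (cell-center registration)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cs = self.cell_size
        # fractional cell-center coordinates
        fc = (x - (self.x_origin + cs / 2)) / cs
        fr = ((self.y_origin - cs / 2) - y) / cs
        nrows, ncols = self.shape
        fc = np.clip(fc, 0, ncols - 1)
        fr = np.clip(fr, 0, nrows - 1)
        c0 = np.clip(np.floor(fc).astype(int), 0, ncols - 2) if ncols > 1 else np.zeros_like(fc, int)
        r0 = np.clip(np.floor(fr).astype(int), 0, nrows - 2) if nrows > 1 else np.zeros_like(fr, int)
        tc = fc - c0
        tr = fr - r0
        v = self.values
        c1 = np.minimum(c0 + 1, ncols - 1)
        r1 = np.minimum(r0 + 1, nrows - 1)
        top = v[r0, c0] * (1 - tc) + v[r0, c1] * tc
        bot = v[r1, c0] * (1 - tc) + v[r1, c1] * tc
        return top * (1 - tr) + bot * tr

    # -- statistics -----------------------------------------------------
    def mean(self) -> float:
        return float(self.valid_values().mean())

    def sd(self) -> float:
        return float(self.valid_values().std(ddof=0))

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Grid":
        return replace(self, values=np.asarray(values, dtype=float),
                       name=self.name if name is None else name)

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())


@dataclass
class CategoricalGrid(Grid):
    """Integer-coded raster with a legend mapping code -> class name."""

    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        codes = np.unique(self.values[self.valid_mask()]).astype(int)
        missing = [int(c) for c in codes if int(c) not in self.legend]
        if missing:
            raise ValueError(f"codes missing from legend: {missing}")


@dataclass
class ScenarioStack:
    """Named, aligned predictor grids tagged with a scenario identity.

    The present-day stack uses ``label='present'`` and ``year=None``;
    future stacks carry the GCM label, year and RCP.
    """

    grids: dict[str, Grid]
    label: str = "present"
    year: int | None = None
    rcp: float | None = None

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("empty stack")
        ok, report = alignment_report(list(self.grids.values()))
        if not ok:
            raise ValueError(f"stack grids are not aligned: {report}")

    @property
    def variables(self) -> list[str]:
        return list(self.grids)

    @property
    def template(self) -> Grid:
        return next(iter(self.grids.values()))

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.template.shape, dtype=bool)
        for g in self.grids.values():
            mask &= g.valid_mask()
        return mask

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> "np.ndarray":
        """(n_cells, n_variables) matrix of raw values at the given cells."""
        return np.column_stack([g.values[rows, cols] for g in self.grids.values()])

    def scenario_id(self) -> str:
        if self.year is None:
            return self.label
        return f"{self.label}_{self.year}_rcp{self.rcp}"


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_grid(path: str | Path, format: str = "ascii_grid", name: str = "") -> Grid:
    """Read a raster. Only the ``ascii_grid`` (ESRI ASCII) format is supported."""
    if format != "ascii_grid":
        raise ValueError(f"unsupported raster format: {format!r} (use 'ascii_grid')")
    path = Path(path)
    text = path.read_text()
    header: dict[str, float] = {}
    lines = text.splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"unparseable header value for {parts[0]!r}") from exc
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridFormatError(f"missing header field {key!r} in {path.name}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    body = "\n".join(lines[i:])
    try:
        values = np.loadtxt(io.StringIO(body), dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"unparseable data rows in {path.name}") from exc
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        raise GridFormatError(
            f"shape mismatch in {path.name}: header says ({nrows}, {ncols}), "
            f"data is {values.shape}"
        )
    return Grid(
        values=values,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=nodata,
        name=name or path.stem,
    )


def write_grid(grid: Grid, path: str | Path, format: str = "ascii_grid") -> Path:
    """Write a raster as an ESRI ASCII grid; reals keep full repr precision."""
    if format != "ascii_grid":
        raise ValueError(f"unsupported raster format: {format!r} (use 'ascii_grid')")
    path = Path(path)
    nrows, ncols = grid.shape
    yll = grid.y_origin - nrows * grid.cell_size
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"nodata_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def alignment_report(grids: Iterable[Grid]) -> tuple[bool, list[str]]:
    """Pairwise alignment check against the first grid; report offending fields."""
    grids = list(grids)
    if not grids:
        raise ValueError("need at least one grid")
    ref = grids[0]
    problems: list[str] = []
    for g in grids[1:]:
        for fld in ("x_origin", "y_origin", "cell_size"):
            if getattr(g, fld) != getattr(ref, fld):
                problems.append(f"{g.name or 'grid'}: {fld} "
                                f"{getattr(g, fld)!r} != {getattr(ref, fld)!r}")
        if g.shape != ref.shape:
            problems.append(f"{g.name or 'grid'}: shape {g.shape} != {ref.shape}")
    return not problems, problems


def align_check(grids: Iterable[Grid]) -> bool:
    """True iff all grids share origin, cell size and shape exactly."""
    ok, _ = alignment_report(grids)
    return ok


def haversine_m(x1, y1, x2, y2) -> np.ndarray:
    """Great-circle distance in meters between lon/lat points (WGS84 sphere)."""
    r = 6_371_008.8
    lam1, phi1, lam2, phi2 = map(np.radians, (x1, y1, x2, y2))
    a = (np.sin((phi2 - phi1) / 2) ** 2
         + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2)
    return 2 * r * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
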