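"""Synthetic coastal study area: terrain, climate, land use, and presences.

The generator emulates the statistical structure the analysis assumes, not
any real geography: a roughly north–south coastline with configurable cliffed
segments; a fine digital terrain model (elevation zero at the waterline,
rising inland, near-vertical faces where cliffs are configured); three
bioclimate-like fields built as a linear spatial gradient plus a stationary
Gaussian random field, standardized to the configured mean and standard
deviation; a five-class land-use mosaic; and presence records sampled from a
declared log-linear (Gibbs) suitability model so downstream fits can be
checked against a known truth.

Future scenarios shift the climate fields' first two moments per GCM label,
period and RCP; the distance-to-cliffs predictor is static and is never
touched by any scenario operation.  Every artifact is bit-reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Polygon, box

from .grids import CategoricalGrid, Grid, LANDUSE_CLASSES, ScenarioStack
from .occurrences import OccurrenceSet

__all__ = [
    "ClimateFieldSpec",
    "CliffSegment",
    "SyntheticWorldSpec",
    "SyntheticWorld",
    "TrueModel",
    "ScenarioDelta",
    "DirtySpec",
    "gen_world",
    "sample_presences",
    "apply_delta",
    "default_scenario_deltas",
    "evolve_landuse",
    "STATIC_VARIABLE",
]

#: name of the static (never shifted) predictor
STATIC_VARIABLE = "dist_cliffs"

#: present-day first two moments of the three bioclimate-like fields
PRESENT_CLIMATE = {"bio9": (21.69, 0.72), "bio12": (60.01, 6.88), "bio15": (64.73, 2.55)}

#: future (mean, sd) per variable, keyed (gcm, year, rcp); the five GCM labels
#: cross two periods and two RCPs into the 20 projection scenarios
GCM_LABELS = ("ACCESS1-0", "BCC-CSM1-1", "CCSM4", "MIROC-ESM", "MRI-CGCM3")
FUTURE_CLIMATE: dict[tuple[str, int, float], dict[str, tuple[float, float]]] = {}
_FUTURE_ROWS = {
    "bio9": {
        (2050, 4.5): [(23.85, 0.84), (23.85, 0.78), (23.34, 0.84), (25.16, 0.85), (23.05, 0.79)],
        (2050, 8.5): [(24.30, 0.89), (24.42, 0.80), (23.68, 0.92), (26.04, 0.83), (23.43, 0.84)],
        (2070, 4.5): [(24.43, 0.87), (23.98, 0.78), (23.30, 0.86), (26.44, 0.82), (23.66, 0.79)],
        (2070, 8.5): [(24.84, 0.96), (25.76, 0.84), (24.24, 1.00), (27.46, 0.86), (24.14, 0.88)],
    },
    "bio12": {
        (2050, 4.5): [(48.77, 4.79), (56.35, 6.36), (49.94, 6.85), (56.19, 6.23), (64.68, 6.98)],
        (2050, 8.5): [(46.15, 5.13), (50.68, 6.61), (46.88, 6.82), (48.06, 5.58), (69.68, 7.84)],
        (2070, 4.5): [(49.65, 6.44), (54.42, 6.59), (48.24, 6.91), (48.91, 6.04), (61.90, 7.16)],
        (2070, 8.5): [(42.91, 6.23), (44.37, 5.69), (45.41, 6.71), (41.00, 5.60), (63.97, 7.99)],
    },
    "bio15": {
        (2050, 4.5): [(80.84, 4.08), (72.33, 2.77), (69.37, 2.60), (69.59, 2.72), (72.04, 2.04)],
        (2050, 8.5): [(78.49, 3.39), (70.63, 1.84), (71.08, 2.48), (66.92, 2.56), (79.26, 2.38)],
        (2070, 4.5): [(74.29, 2.11), (62.88, 1.95), (69.93, 2.27), (67.88, 2.87), (71.78, 2.44)],
        (2070, 8.5): [(96.35, 1.91), (77.05, 1.59), (73.66, 3.02), (68.73, 2.00), (85.56, 4.08)],
    },
}
for _var, _combos in _FUTURE_ROWS.items():
    for (_year, _rcp), _cells in _combos.items():
        for _gcm, _ms in zip(GCM_LABELS, _cells):
            FUTURE_CLIMATE.setdefault((_gcm, _year, _rcp), {})[_var] = _ms


@dataclass(frozen=True)
class ClimateFieldSpec:
    name: str
    mean: float
    sd: float
    gradient_angle_deg: float = 0.0      # direction of the linear trend
    gradient_weight: float = 0.5         # share of variance in the trend
    correlation_length_m: float = 5000.0 # smoothing scale of the noise field

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class CliffSegment:
    """Alongshore run of cliffed coast (positions in meters of northing)."""

    y_start: float
    y_end: float
    top_height_m: float = 30.0
    face_width_m: float = 20.0

    def __post_init__(self) -> None:
        if self.top_height_m <= 0 or self.face_width_m <= 0:
            raise ValueError("cliff height and face width must be > 0")
        if self.y_end <= self.y_start:
            raise ValueError("cliff segment must have y_end > y_start")

    @property
    def slope_pct(self) -> float:
        return 100.0 * self.top_height_m / self.face_width_m


@dataclass
class SyntheticWorldSpec:
    """All knobs of the synthetic study area.

    Defaults describe a realistic coastal study region: a ~1 km analysis lattice of 9860
    cells (116 x 85), a 10 m terrain model on a coastal strip, cliffed
    segments of 30 m tops over 20 m faces (slope 150%), and climate fields
    with the present-day moments of the three bioclimate variables.
    """

    coarse_shape: tuple[int, int] = (116, 85)
    coarse_cell_m: float = 1000.0
    fine_cell_m: float = 10.0
    fine_strip_width_m: float = 2000.0
    coast_x0_m: float = 500.0
    coast_amplitude_m: float = 300.0
    coast_wavelength_m: float = 30000.0
    coast_vertex_spacing_m: float = 50.0
    background_slope: float = 0.02        # gentle inland rise outside cliffs
    cliff_segments: tuple[CliffSegment, ...] = (
        CliffSegment(10_000.0, 45_000.0, 30.0, 20.0),
        CliffSegment(60_000.0, 95_000.0, 30.0, 20.0),
    )
    # gradients mostly alongshore so climate varies within the coastal strip
    # the species occupies (a cross-shore gradient would be confounded with
    # the distance-to-cliffs predictor)
    climate_fields: tuple[ClimateFieldSpec, ...] = (
        ClimateFieldSpec("bio9", *PRESENT_CLIMATE["bio9"], gradient_angle_deg=80.0),
        ClimateFieldSpec("bio12", *PRESENT_CLIMATE["bio12"], gradient_angle_deg=90.0),
        ClimateFieldSpec("bio15", *PRESENT_CLIMATE["bio15"], gradient_angle_deg=20.0),
    )
    landuse_proportions: tuple[float, ...] = (0.03, 0.07, 0.45, 0.33, 0.12)
    landuse_correlation_length_m: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fine_cell_m < self.coarse_cell_m:
            raise ValueError("fine cell size must be smaller than coarse cell size")
        height = self.coarse_shape[0] * self.coarse_cell_m
        for seg in self.cliff_segments:
            if seg.y_start < 0 or seg.y_end > height:
                raise ValueError(f"cliff segment {seg} outside coastline extent [0, {height}]")
        if abs(sum(self.landuse_proportions) - 1.0) > 1e-9 or len(self.landuse_proportions) != 5:
            raise ValueError("landuse_proportions must be 5 values summing to 1")

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the coarse domain in meters."""
        return (self.coarse_shape[1] * self.coarse_cell_m,
                self.coarse_shape[0] * self.coarse_cell_m)


@dataclass
class TrueModel:
    """The generating log-linear suitability model over scaled predictors.

    ``eta*(cell) = Σ_v linear[v]·z_v + Σ_v quadratic[v]·z_v²`` with each
    variable min–max scaled to [0, 1] over the valid cells of the stack it is
    evaluated on.  The distance-to-cliffs coefficient must be negative and
    nonzero: true suitability decays inland.
    """

    # defaults: strong coastal decay plus clear thermal / precipitation optima
    # (humps peaking mid-range), so the generating LQ form is identifiable
    linear: dict[str, float] = field(default_factory=lambda: {
        STATIC_VARIABLE: -7.0, "bio9": 12.0, "bio12": 10.0, "bio15": 2.0})
    quadratic: dict[str, float] = field(default_factory=lambda: {
        "bio9": -12.0, "bio12": -10.0, "bio15": -2.0})

    def __post_init__(self) -> None:
        if self.linear.get(STATIC_VARIABLE, 0.0) >= 0:
            raise ValueError("true model needs a negative distance-to-cliffs coefficient")

    @property
    def variables(self) -> list[str]:
        return sorted(set(self.linear) | set(self.quadratic))

    def eta(self, stack: ScenarioStack) -> np.ndarray:
        """Linear predictor over valid cells (row-major order of the mask)."""
        mask = stack.valid_mask()
        out = np.zeros(int(mask.sum()))
        for v in self.variables:
            vals = stack.grids[v].values[mask]
            lo, hi = vals.min(), vals.max()
            z = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
            out += self.linear.get(v, 0.0) * z + self.quadratic.get(v, 0.0) * z ** 2
        return out


@dataclass(frozen=True)
class ScenarioDelta:
    """Climate shift for one (GCM, year, RCP) scenario.

    ``shifts`` maps variable -> (additive mean shift, anomaly scale); the
    transformed field is ``mean + add + (v − mean)·scale``, so ``add`` moves
    the mean and ``scale`` inflates or deflates the standard deviation.  The
    static distance-to-cliffs variable may never appear.
    """

    label: str
    year: int
    rcp: float
    shifts: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.year not in (2050, 2070):
            raise ValueError("year must be 2050 or 2070")
        if self.rcp not in (4.5, 8.5):
            raise ValueError("rcp must be 4.5 or 8.5")
        if STATIC_VARIABLE in self.shifts:
            raise ValueError("scenario deltas may not target the static "
                             f"variable {STATIC_VARIABLE!r}")


@dataclass(frozen=True)
class DirtySpec:
    """Fractions of records to corrupt (disjoint subsets) for cleaning tests."""

    frac_out_of_range: float = 0.0
    frac_unverified: float = 0.0
    frac_inaccurate: float = 0.0

    def __post_init__(self) -> None:
        total = self.frac_out_of_range + self.frac_unverified + self.frac_inaccurate
        if total > 1.0:
            raise ValueError("dirty fractions must sum to <= 1")


@dataclass
class SyntheticWorld:
    spec: SyntheticWorldSpec
    dtm: Grid
    coastline: LineString
    climate: dict[str, Grid]
    landuse: CategoricalGrid

    def range_polygon(self) -> Polygon:
        """The coarse-domain bounding box — the species' known range."""
        w, h = self.spec.extent
        return box(0.0, 0.0, w, h)

    def present_stack(self, dist_cliffs: Grid) -> ScenarioStack:
        grids = dict(self.climate)
        grids[STATIC_VARIABLE] = dist_cliffs
        return ScenarioStack(grids=grids, label="present")


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def _coast_x(spec: SyntheticWorldSpec, y: np.ndarray) -> np.ndarray:
    return spec.coast_x0_m + spec.coast_amplitude_m * np.sin(
        2 * np.pi * y / spec.coast_wavelength_m)


def _random_field(shape: tuple[int, int], cell_m: float, corr_len_m: float,
                  rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sigma = max(corr_len_m / cell_m, 1e-6)
    f = gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _climate_grid(fspec: ClimateFieldSpec, spec: SyntheticWorldSpec,
                  rng: np.random.Generator) -> Grid:
    nrows, ncols = spec.coarse_shape
    cs = spec.coarse_cell_m
    w, h = spec.extent
    xs = cs * (np.arange(ncols) + 0.5)
    ys = h - cs * (np.arange(nrows) + 0.5)
    X, Y = np.meshgrid(xs, ys)
    a = np.radians(fspec.gradient_angle_deg)
    grad = (np.cos(a) * X + np.sin(a) * Y)
    gsd = grad.std()
    grad = (grad - grad.mean()) / gsd if gsd > 0 else np.zeros_like(grad)
    noise = _random_field(spec.coarse_shape, cs, fspec.correlation_length_m, rng)
    gw = fspec.gradient_weight
    fld = np.sqrt(gw) * grad + np.sqrt(1 - gw) * noise
    # standardize to the configured first two moments exactly
    fsd = fld.std()
    fld = (fld - fld.mean()) / fsd if fsd > 0 else np.zeros_like(fld)
    fld = fspec.mean + fspec.sd * fld
    return Grid(values=fld, x_origin=0.0, y_origin=h, cell_size=cs,
                name=fspec.name)


def _elevation(spec: SyntheticWorldSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Analytic terrain surface: 0 at the waterline, cliffs where configured."""
    d = X - _coast_x(spec, Y)             # signed inland distance
    z = np.where(d > 0, spec.background_slope * d, 0.0)
    for seg in spec.cliff_segments:
        in_seg = (Y >= seg.y_start) & (Y <= seg.y_end) & (d > 0)
        face = np.clip(d / seg.face_width_m, 0.0, 1.0) * seg.top_height_m
        beyond = np.maximum(d - seg.face_width_m, 0.0) * spec.background_slope
        z = np.where(in_seg, face + beyond, z)
    return z


def gen_world(spec: SyntheticWorldSpec) -> SyntheticWorld:
    """Generate the full synthetic study area; deterministic per spec.seed."""
    rng_master = np.random.SeedSequence(spec.seed)
    streams = rng_master.spawn(len(spec.climate_fields) + 1)

    w, h = spec.extent
    # coastline polyline, ordered north -> south so land lies to the left
    ys = np.arange(h, -spec.coast_vertex_spacing_m / 2, -spec.coast_vertex_spacing_m)
    ys = np.clip(ys, 0.0, h)
    coastline = LineString(np.column_stack([_coast_x(spec, ys), ys]))

    # fine DTM over the coastal strip
    ncols_f = int(np.ceil(spec.fine_strip_width_m / spec.fine_cell_m))
    nrows_f = int(np.ceil(h / spec.fine_cell_m))
    cf = spec.fine_cell_m
    xs_f = cf * (np.arange(ncols_f) + 0.5)
    ys_f = h - cf * (np.arange(nrows_f) + 0.5)
    Xf, Yf = np.meshgrid(xs_f, ys_f)
    dtm = Grid(values=_elevation(spec, Xf, Yf), x_origin=0.0, y_origin=h,
               cell_size=cf, name="dtm")

    climate = {
        f.name: _climate_grid(f, spec, np.random.default_rng(s))
        for f, s in zip(spec.climate_fields, streams[:-1])
    }

    # land-use mosaic: smoothed noise binned at the configured proportions
    rng_lu = np.random.default_rng(streams[-1])
    lu_field = _random_field(spec.coarse_shape, spec.coarse_cell_m,
                             spec.landuse_correlation_length_m, rng_lu)
    edges = np.quantile(lu_field, np.cumsum(spec.landuse_proportions)[:-1])
    codes = np.digitize(lu_field, edges).astype(float)
    landuse = CategoricalGrid(values=codes, x_origin=0.0, y_origin=h,
                              cell_size=spec.coarse_cell_m, name="landuse",
                              legend={i: n for i, n in enumerate(LANDUSE_CLASSES)})
    return SyntheticWorld(spec=spec, dtm=dtm, coastline=coastline,
                          climate=climate, landuse=landuse)


# ---------------------------------------------------------------------------
# Presence sampling
# ---------------------------------------------------------------------------

def sample_presences(
    true_model: TrueModel,
    stack: ScenarioStack,
    m: int,
    seed: int = 0,
    max_uncertainty_m: float = 1000.0,
    dirty: DirtySpec | None = None,
) -> OccurrenceSet:
    """Sample m presence records with cell weight ∝ exp(eta*).

    Cells are drawn multinomially (with replacement — several records may
    share a cell, as opportunistic data do), each record jittered uniformly
    within its cell and given an uncertainty <= ``max_uncertainty_m``.  The
    ``dirty`` option corrupts disjoint random subsets to exercise the three
    cleaning rules; the injected counts are recorded in the provenance log.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    mask = stack.valid_mask()
    if not mask.any():
        raise ValueError("stack has no valid cells")
    rows, cols = np.nonzero(mask)
    eta = true_model.eta(stack)
    w = np.exp(eta - eta.max())
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=m, replace=True, p=p)
    r, c = rows[pick], cols[pick]
    t = stack.template
    cs = t.cell_size
    x = t.x_origin + cs * (c + rng.uniform(0, 1, size=m))
    y = t.y_origin - cs * (r + rng.uniform(0, 1, size=m))
    unc = rng.uniform(0.0, max_uncertainty_m, size=m)

    df = pd.DataFrame({
        "id": np.arange(m), "x": x, "y": y, "uncertainty_m": unc,
        "verified": True, "source": "synthetic", "discard_reason": None,
        "cell_row": r, "cell_col": c,
    })

    log: dict = {"sampling": {"seed": seed, "m": m}}
    if dirty is not None:
        n_out = int(round(dirty.frac_out_of_range * m))
        n_unv = int(round(dirty.frac_unverified * m))
        n_bad = int(round(dirty.frac_inaccurate * m))
        idx = rng.permutation(m)
        i_out = idx[:n_out]
        i_unv = idx[n_out:n_out + n_unv]
        i_bad = idx[n_out + n_unv:n_out + n_unv + n_bad]
        width = t.cell_size * t.shape[1]
        df.loc[i_out, "x"] += 2 * width            # well outside the range polygon
        df.loc[i_unv, "verified"] = False
        df.loc[i_bad, "uncertainty_m"] = rng.uniform(
            max_uncertainty_m * 1.001, max_uncertainty_m * 5, size=n_bad)
        log["dirty"] = {"out_of_range": n_out, "unverified": n_unv,
                        "inaccurate": n_bad,
                        "ids": {"out_of_range": sorted(int(i) for i in i_out),
                                "unverified": sorted(int(i) for i in i_unv),
                                "inaccurate": sorted(int(i) for i in i_bad)}}
    return OccurrenceSet(records=df, lonlat=False, log=log)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def apply_delta(stack: ScenarioStack, delta: ScenarioDelta) -> ScenarioStack:
    """Shift climate grids per the delta; the static grid passes through as-is."""
    missing = [v for v in delta.shifts if v not in stack.grids]
    if missing:
        raise ValueError(f"delta targets unknown variable(s): {missing}")
    out: dict[str, Grid] = {}
    for name, g in stack.grids.items():
        if name in delta.shifts:
            add, scale = delta.shifts[name]
            mu = g.mean()
            v = np.where(g.valid_mask(), (g.values - mu) * scale + mu + add, g.values)
            out[name] = g.with_values(v)
        else:
            out[name] = g  # static variables: the identical object
    return ScenarioStack(grids=out, label=delta.label, year=delta.year, rcp=delta.rcp)


def default_scenario_deltas(
    present_means: dict[str, tuple[float, float]] | None = None,
) -> list[ScenarioDelta]:
    """The 20 scenario deltas (5 GCMs x 2 periods x 2 RCPs).

    Shifts move each climate variable from its present-day moments to the
    scenario's future mean and sd.
    """
    present = present_means or PRESENT_CLIMATE
    deltas = []
    for (gcm, year, rcp), targets in sorted(FUTURE_CLIMATE.items()):
        shifts = {}
        for var, (f_mean, f_sd) in targets.items():
            p_mean, p_sd = present[var]
            shifts[var] = (f_mean - p_mean, f_sd / p_sd if p_sd > 0 else 1.0)
        deltas.append(ScenarioDelta(label=gcm, year=year, rcp=rcp, shifts=shifts))
    return deltas


def evolve_landuse(landuse: CategoricalGrid, seed: int = 0,
                   p_change: float = 0.05) -> CategoricalGrid:
    """Simple per-class transition sampler for future land-use test grids.

    Each cell independently keeps its class with probability 1 − p_change or
    redraws it from the current class frequencies.  A declared convenience
    stand-in, NOT a land-use change simulation model.
    """
    rng = np.random.default_rng(seed)
    valid = landuse.valid_mask()
    vals = landuse.values.copy()
    codes, counts = np.unique(vals[valid].astype(int), return_counts=True)
    freq = counts / counts.sum()
    flip = valid & (rng.uniform(size=vals.shape) < p_change)
    vals[flip] = rng.choice(codes, size=int(flip.sum()), p=freq).astype(float)
    return CategoricalGrid(values=vals, x_origin=landuse.x_origin,
                           y_origin=landuse.y_origin, cell_size=landuse.cell_size,
                           nodata=landuse.nodata, name=landuse.name,
                           legend=dict(landuse.legend))
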