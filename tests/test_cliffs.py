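"""Transect construction, Top/Toe detection, and distance rasters."""

import numpy as np
import pytest
from shapely.geometry import LineString

from cliffsdm import (
    CliffPoint,
    Grid,
    SyntheticWorldSpec,
    build_transects,
    delineate_cliffs,
    detect_top_toe,
    distance_raster,
    extract_profile,
    gen_world,
    shore_distance_raster,
)
from cliffsdm.cliffs import Transect, TransectProfile
from cliffsdm.synthetic import CliffSegment


def flat_dtm(value=0.0, n=60, cell=10.0):
    return Grid(np.full((n, n), float(value)), 0.0, n * cell, cell, name="dtm")


def make_profile(d, z):
    d = np.asarray(d, dtype=float)
    return TransectProfile(0, d, np.asarray(z, dtype=float), d.copy(),
                           d.copy(), np.zeros_like(d))


class TestTransects:
    def test_straight_100m_coast_gives_21_transects(self):
        ts = build_transects(LineString([(0, 0), (100, 0)]), spacing_m=5.0,
                             length_m=50.0, step_m=5.0)
        assert len(ts) == 21

    def test_east_west_coast_land_north_points_north(self):
        ts = build_transects(LineString([(0, 0), (100, 0)]), spacing_m=10.0,
                             length_m=50.0, step_m=5.0)
        for t in ts:
            assert t.direction == pytest.approx((0.0, 1.0))

    def test_circular_arc_perpendicular_to_analytic_tangent(self):
        r = 10_000.0
        theta = np.linspace(0.0, np.pi / 2, 20_001)
        arc = LineString(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        ts = build_transects(arc, spacing_m=500.0, length_m=100.0, step_m=10.0)
        for t in ts[2:-2]:
            anchor = np.asarray(t.anchor)
            inward = -anchor / np.linalg.norm(anchor)   # land inside the circle
            cosang = np.clip(np.dot(t.direction, inward), -1.0, 1.0)
            assert np.arccos(cosang) < 1e-6

    def test_degenerate_coastline_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_transects(LineString([(0, 0), (0, 0)]), 5.0, 50.0, 5.0)


class TestProfiles:
    def test_flat_dtm_constant_profile(self):
        t = Transect(0, (5.0, 300.0), (1.0, 0.0), 100.0, 10.0)
        p = extract_profile(flat_dtm(7.0), t)
        assert np.all(p.elevation_m == 7.0)

    def test_planar_ramp_is_sampled_exactly(self):
        n, cell = 60, 1.0
        xs = cell * (np.arange(n) + 0.5)
        dtm = Grid(np.tile(0.5 * xs, (n, 1)), 0.0, n * cell, cell)
        t = Transect(0, (0.0, 30.5), (1.0, 0.0), 50.0, 10.0)
        p = extract_profile(dtm, t)
        i40 = int(np.flatnonzero(p.distance_m == 40.0)[0])
        assert p.elevation_m[i40] == pytest.approx(20.0)

    def test_transect_outside_dtm_errors(self):
        t = Transect(0, (1e6, 1e6), (1.0, 0.0), 50.0, 10.0)
        with pytest.raises(ValueError, match="outside"):
            extract_profile(flat_dtm(), t)

    def test_synthetic_cliff_face_reproduced(self, world):
        """The generated 30 m / 20 m face appears in profiles at near-configured height."""
        pts = delineate_cliffs(world.dtm, world.coastline, spacing_m=500.0,
                               length_m=300.0, step_m=5.0)
        tops = [p for p in pts if p.role == "Top"]
        assert tops
        elev = np.array([p.elevation_m for p in tops])
        assert np.all(np.abs(elev - 30.0) < 5.0)   # bilinear + step tolerance
        assert all(p.slope_pct >= 70.0 for p in tops)


class TestTopToe:
    def test_flat_profile_has_no_cliff(self):
        assert detect_top_toe(make_profile(np.arange(0, 100, 10),
                                           np.zeros(10))) is None

    def test_qualifying_rise_detected_with_slope(self):
        d = np.arange(0, 60, 10.0)
        z = np.array([0.0, 2.0, 17.0, 32.0, 32.5, 33.0])  # 30 m over 20 m
        pair = detect_top_toe(make_profile(d, z))
        assert pair is not None
        top, toe = pair
        assert (top.role, toe.role) == ("Top", "Toe")
        assert top.slope_pct == pytest.approx(150.0)
        assert top.elevation_m == pytest.approx(32.0)

    def test_steep_but_low_top_rejected(self):
        # 200% slope but Top at 10 m fails the 15 m altitude rule
        d = np.arange(0, 30, 5.0)
        z = np.array([0.0, 5.0, 10.0, 10.2, 10.3, 10.4])
        assert detect_top_toe(make_profile(d, z)) is None

    def test_generator_truth_recall_and_precision(self):
        spec = SyntheticWorldSpec(
            coarse_shape=(100, 30), seed=3,
            cliff_segments=(CliffSegment(10_000.0, 30_000.0, 30.0, 20.0),
                            CliffSegment(50_000.0, 70_000.0, 10.0, 10.0)))
        w = gen_world(spec)
        pts = delineate_cliffs(w.dtm, w.coastline, spacing_m=200.0,
                               length_m=300.0, step_m=5.0)
        tops_y = np.array([p.y for p in pts if p.role == "Top"])
        assert tops_y.size > 0
        # every detection inside the qualifying segment; none elsewhere
        assert np.all((tops_y > 9_500.0) & (tops_y < 30_500.0))

    def test_world_without_cliffs_yields_no_tops(self):
        spec = SyntheticWorldSpec(coarse_shape=(40, 20), seed=4, cliff_segments=())
        w = gen_world(spec)
        pts = delineate_cliffs(w.dtm, w.coastline, spacing_m=500.0,
                               length_m=300.0, step_m=10.0)
        assert pts == []


def top(x, y):
    return CliffPoint(x, y, "Top", 20.0, 0, 100.0)


class TestDistanceRasters:
    def test_cell_on_point_is_zero_and_matches_brute_force_exactly(self):
        template = Grid(np.zeros((3, 3)), 0.0, 3000.0, 1000.0)
        pts = [top(500.0, 2500.0), top(2100.0, 700.0)]
        d = distance_raster(template, pts)
        assert d.values[0, 0] == 0.0
        cx, cy = template.cell_centers()
        for i in range(3):
            for j in range(3):
                best = min(((cx[i, j] - p.x) * (cx[i, j] - p.x)
                            + (cy[i, j] - p.y) * (cy[i, j] - p.y)) ** 0.5
                           for p in pts)
                assert d.values[i, j] == best   # exact, not approximate

    def test_min_composition_of_two_point_sets(self):
        template = Grid(np.zeros((5, 5)), 0.0, 5000.0, 1000.0)
        a, b = top(100.0, 100.0), top(4200.0, 4700.0)
        d_both = distance_raster(template, [a, b])
        d_min = np.minimum(distance_raster(template, [a]).values,
                           distance_raster(template, [b]).values)
        assert np.array_equal(d_both.values, d_min)

    def test_lipschitz_across_neighbor_cells(self):
        rng = np.random.default_rng(0)
        template = Grid(np.zeros((12, 12)), 0.0, 12_000.0, 1000.0)
        pts = [top(x, y) for x, y in rng.uniform(0, 12_000, size=(7, 2))]
        d = distance_raster(template, pts).values
        assert np.all(np.abs(np.diff(d, axis=0)) <= 1000.0 + 1e-9)
        assert np.all(np.abs(np.diff(d, axis=1)) <= 1000.0 + 1e-9)

    def test_adding_a_point_never_increases_distance(self):
        rng = np.random.default_rng(1)
        template = Grid(np.zeros((10, 10)), 0.0, 10_000.0, 1000.0)
        base = [top(x, y) for x, y in rng.uniform(0, 10_000, size=(4, 2))]
        extra = base + [top(3333.0, 7777.0)]
        assert np.all(distance_raster(template, extra).values
                      <= distance_raster(template, base).values)

    def test_empty_point_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_raster(Grid(np.zeros((2, 2)), 0, 2000, 1000), [])


class TestShoreDistance:
    def test_straight_north_south_coast(self):
        template = Grid(np.zeros((2, 1)), 3000.0, 2000.0, 1000.0)
        line = LineString([(0.0, -1e6), (0.0, 1e6)])
        d = shore_distance_raster(template, line)
        assert np.all(d.values == 3500.0)

    def test_cell_center_on_the_line_is_zero(self):
        template = Grid(np.zeros((1, 1)), 0.0, 1000.0, 1000.0)
        line = LineString([(500.0, -10.0), (500.0, 1010.0)])
        assert shore_distance_raster(template, line).values[0, 0] == 0.0

    def test_wiggly_coast_matches_densified_oracle(self):
        ys = np.linspace(0.0, 10_000.0, 101)
        xs = 500.0 + 300.0 * np.sin(ys / 800.0)
        line = LineString(np.column_stack([xs, ys]))
        template = Grid(np.zeros((10, 10)), 0.0, 10_000.0, 1000.0)
        d = shore_distance_raster(template, line).values
        # oracle: nearest of the vertices of a 1 m densification
        step = 1.0
        n = int(line.length / step) + 1
        dense = np.array([line.interpolate(i * step).coords[0] for i in range(n)])
        cx, cy = template.cell_centers()
        oracle = np.min(np.hypot(cx.ravel()[:, None] - dense[None, :, 0],
                                 cy.ravel()[:, None] - dense[None, :, 1]), axis=1)
        assert np.all(np.abs(d.ravel() - oracle) <= step / 2)
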