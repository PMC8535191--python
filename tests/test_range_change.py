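"""Binarization, dispersal polygon, change accounting and land-use overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cliffsdm import (
    BinaryMap,
    CategoricalGrid,
    Grid,
    binarize,
    build_dispersal_polygon,
    change_account,
    count_above,
    landuse_crosstab,
)
from cliffsdm.grids import LANDUSE_CLASSES


def grid_of(vals, nodata=-9999.0):
    vals = np.asarray(vals, dtype=float)
    return Grid(vals, 0.0, vals.shape[0] * 1000.0, 1000.0, nodata=nodata)


def binary_of(vals, tau=0.5):
    return BinaryMap(grid_of(vals), tau)


class TestBinarize:
    def test_all_below_threshold(self):
        b = binarize(grid_of(np.full((3, 3), 0.2)), 0.5)
        assert b.presence_count() == 0

    def test_boundary_cell_is_suitable(self):
        b = binarize(grid_of([[0.35, 0.3499]]), 0.35)
        assert b.grid.values.tolist() == [[1.0, 0.0]]

    def test_nodata_propagates(self):
        b = binarize(grid_of([[0.9, -9999.0]]), 0.5)
        assert b.grid.values[0, 1] == -9999.0

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_presence_count_non_increasing_in_threshold(self, t1, t2):
        rng = np.random.default_rng(0)
        g = grid_of(rng.uniform(0, 1, size=(8, 8)))
        lo, hi = sorted((t1, t2))
        assert binarize(g, hi).presence_count() <= binarize(g, lo).presence_count()


class TestCountAbove:
    def test_strictly_above(self):
        assert count_above(grid_of(np.full((4, 4), 0.5)), 0.5) == 0
        g = grid_of(np.where(np.arange(16).reshape(4, 4) < 7, 0.61, 0.2))
        assert count_above(g, 0.60) == 7

    def test_agrees_with_exclusive_binarize_complement(self):
        rng = np.random.default_rng(1)
        g = grid_of(rng.uniform(0, 1, size=(10, 10)))
        assert count_above(g, 0.6) == int(np.sum(g.values > 0.6))


class TestDispersalPolygon:
    def shore(self, n=10):
        return grid_of(np.tile(1000.0 * (np.arange(n) + 0.5), (n, 1)))

    def test_hull_excludes_interior_point(self):
        pts = np.array([(0, 0), (0, 5000), (5000, 5000), (5000, 0), (2500, 2500)])
        poly = build_dispersal_polygon(pts, self.shore(), buffer_m=0.0)
        assert len(poly.polygon.exterior.coords) - 1 == 4

    def test_edge_midpoint_inside_with_zero_buffer(self):
        pts = np.array([(0, 0), (0, 4000), (4000, 4000), (4000, 0)])
        poly = build_dispersal_polygon(pts, self.shore(), buffer_m=0.0)
        assert poly.polygon.covers(__import__("shapely").Point(0.0, 2000.0))

    def test_buffered_square_area_formula(self):
        s, b = 4000.0, 2000.0
        pts = np.array([(0, 0), (0, s), (s, s), (s, 0)])
        poly = build_dispersal_polygon(pts, self.shore(), buffer_m=b)
        expected = s**2 + 4 * s * b + np.pi * b**2
        assert poly.polygon.area == pytest.approx(expected, rel=0.005)

    def test_mask_respects_shore_crop(self):
        pts = np.array([(0, 0), (0, 9000), (9000, 9000), (9000, 0)])
        poly = build_dispersal_polygon(pts, self.shore(), buffer_m=0.0,
                                       max_shore_m=7000.0)
        cx, _ = self.shore().cell_centers()
        assert not poly.cell_mask[cx > 7000.0].any()
        assert poly.cell_mask.any()

    def test_collinear_points_rejected(self):
        pts = np.array([(0, 0), (1000, 1000), (2000, 2000)])
        with pytest.raises(ValueError, match="collinear"):
            build_dispersal_polygon(pts, self.shore())


class TestChangeAccount:
    def test_identical_maps_no_change(self):
        cur = binary_of([[1, 0], [1, 1]])
        s, cmap = change_account(cur, binary_of([[1, 0], [1, 1]]))
        assert (s.maintained, s.lost, s.gained) == (3, 0, 0)
        assert s.net_gain_pct == 0.0
        assert np.all(cmap.values[cur.grid.values == 1] == 1.0)

    def test_hand_enumerated_three_by_three(self):
        cur = binary_of([[1, 1, 1], [1, 1, 0], [0, 0, 0]])
        fut = binary_of([[1, 1, 1], [0, 0, 1], [1, 1, 1]])
        s, cmap = change_account(cur, fut)
        assert (s.maintained, s.lost, s.gained) == (3, 2, 4)
        assert s.net_gain_pct == pytest.approx(40.0)   # (7-5)/5
        assert int(np.sum(cmap.values == 2.0)) == 2
        assert int(np.sum(cmap.values == 3.0)) == 4

    def test_identities_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            cur = binary_of(rng.integers(0, 2, size=(5, 5)))
            fut = binary_of(rng.integers(0, 2, size=(5, 5)))
            s, _ = change_account(cur, fut)
            assert s.maintained + s.lost == cur.presence_count()
            assert s.maintained + s.gained == fut.presence_count()

    def test_constraint_monotone_and_idempotent(self):
        rng = np.random.default_rng(3)
        shore = grid_of(np.tile(1000.0 * (np.arange(6) + 0.5), (6, 1)))
        pts = np.array([(500, 500), (500, 4500), (4500, 2500)])
        poly = build_dispersal_polygon(pts, shore, buffer_m=500.0)
        for _ in range(30):
            cur = binary_of(rng.integers(0, 2, size=(6, 6)))
            fut = binary_of(rng.integers(0, 2, size=(6, 6)))
            s_free, _ = change_account(cur, fut)
            s_con, _ = change_account(cur, fut, poly)
            assert s_con.gained <= s_free.gained
            twice, _ = change_account(cur.masked(poly.cell_mask),
                                      fut.masked(poly.cell_mask), poly)
            assert (twice.maintained, twice.lost, twice.gained) == (
                s_con.maintained, s_con.lost, s_con.gained)

    def test_misaligned_maps_rejected(self):
        cur = binary_of([[1, 0]])
        other = BinaryMap(Grid(np.array([[1.0, 0.0]]), 500.0, 1000.0, 1000.0), 0.5)
        with pytest.raises(ValueError, match="aligned"):
            change_account(cur, other)


class TestLanduseCrosstab:
    def landuse(self, codes):
        codes = np.asarray(codes, dtype=float)
        return CategoricalGrid(codes, 0.0, codes.shape[0] * 1000.0, 1000.0,
                               legend=dict(enumerate(LANDUSE_CLASSES)))

    def test_single_class(self):
        pred = binary_of([[1, 1], [0, 0]])
        row = landuse_crosstab(pred, self.landuse([[2, 2], [3, 4]]))
        assert row["Scrubland"] == 100.0
        assert row["Cropland"] == 0.0 and not row["extinct"]

    def test_mixed_percentages_sum_to_100(self):
        pred = binary_of(np.ones((2, 5)))
        codes = [[2, 2, 2, 2, 2], [3, 3, 3, 4, 4]]
        row = landuse_crosstab(pred, self.landuse(codes))
        assert (row["Scrubland"], row["Cropland"], row["Urban"]) == (50.0, 30.0, 20.0)
        assert sum(row[c] for c in LANDUSE_CLASSES) == pytest.approx(100.0, abs=0.05)

    def test_extinct_scenario_zero_row(self):
        row = landuse_crosstab(binary_of(np.zeros((3, 3))),
                               self.landuse(np.full((3, 3), 2)))
        assert row["extinct"] and all(row[c] == 0.0 for c in LANDUSE_CLASSES)

    def test_nodata_landuse_audited(self):
        lu = self.landuse([[2, 2], [2, 2]])
        lu.values[0, 0] = lu.nodata
        with pytest.warns(UserWarning, match="no land-use class"):
            row = landuse_crosstab(binary_of(np.ones((2, 2))), lu)
        assert row["unclassified_cells"] == 1
        assert row["Scrubland"] == 100.0
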