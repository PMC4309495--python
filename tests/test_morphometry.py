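"""Morphometry: field sampling, segmentation, enclosing circles, cutoff summary."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligono import (
    FieldImage,
    Territory,
    classify_and_summarize,
    measure_territories,
    min_enclosing_circle,
    segment_cells,
    select_fields,
)
from oligono.errors import (
    GeometryError,
    InvalidParameterError,
    UndefinedSummaryError,
)


def brute_force_mec(points):
    """O(n^3) oracle: smallest circle among all pair- and triple-defined ones."""
    pts = [tuple(map(float, p)) for p in points]
    n = len(pts)
    eps = 1e-9

    def contains_all(c, r):
        return all(math.hypot(p[0] - c[0], p[1] - c[1]) <= r + eps for p in pts)

    best = None
    if n == 1:
        return pts[0], 0.0
    for i in range(n):
        for j in range(i + 1, n):
            c = ((pts[i][0] + pts[j][0]) / 2, (pts[i][1] + pts[j][1]) / 2)
            r = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1]) / 2
            if contains_all(c, r) and (best is None or r < best[1]):
                best = (c, r)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                (ax, ay), (bx, by), (cx, cy) = pts[i], pts[j], pts[k]
                d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-12:
                    continue
                ux = (
                    (ax**2 + ay**2) * (by - cy)
                    + (bx**2 + by**2) * (cy - ay)
                    + (cx**2 + cy**2) * (ay - by)
                ) / d
                uy = (
                    (ax**2 + ay**2) * (cx - bx)
                    + (bx**2 + by**2) * (ax - cx)
                    + (cx**2 + cy**2) * (bx - ax)
                ) / d
                r = math.hypot(ax - ux, ay - uy)
                if contains_all((ux, uy), r) and (best is None or r < best[1]):
                    best = ((ux, uy), r)
    return best[0], 2 * best[1]


class TestSelectFields:
    def test_standard_coverslip(self):
        centers = select_fields(13.0, 1.0)
        assert len(centers) == 5
        assert set(centers) == {(0.0, 0.0), (2.0, 0.0), (-2.0, 0.0), (0.0, 2.0), (0.0, -2.0)}

    def test_always_five_fields(self):
        assert len(select_fields(30.0, 2.0)) == 5

    def test_small_coverslip_rejected(self):
        with pytest.raises(GeometryError):
            select_fields(4.0, 1.0)


class TestSegmentCells:
    def test_blank_field_empty(self):
        field = FieldImage(np.zeros((50, 50)), pixel_size=1.0)
        assert segment_cells(field, 10.0, min_pixels=5) == []

    def test_two_separated_disks(self):
        img = np.zeros((60, 60))
        yy, xx = np.mgrid[0:60, 0:60]
        img[(yy - 15) ** 2 + (xx - 15) ** 2 < 36] = 100
        img[(yy - 45) ** 2 + (xx - 45) ** 2 < 36] = 100
        comps = segment_cells(FieldImage(img, 1.0), 50.0, min_pixels=5)
        assert len(comps) == 2
        # deterministic labeling: first component appears first in raster order
        assert tuple(comps[0][0]) < tuple(comps[1][0])

    def test_diagonal_pixels_stay_connected(self):
        img = np.zeros((10, 10))
        for i in range(8):
            img[i, i] = 10  # one-pixel-wide diagonal process
        comps = segment_cells(FieldImage(img, 1.0), 5.0, min_pixels=1)
        assert len(comps) == 1

    def test_debris_filtered(self):
        img = np.zeros((20, 20))
        img[3, 3] = 100  # single-pixel speck
        img[10:14, 10:14] = 100
        comps = segment_cells(FieldImage(img, 1.0), 50.0, min_pixels=4)
        assert len(comps) == 1
        assert len(comps[0]) == 16


class TestMinEnclosingCircle:
    def test_single_point(self):
        center, diam = min_enclosing_circle([(3.0, 4.0)])
        assert diam == 0.0
        assert center == pytest.approx((3.0, 4.0))

    def test_two_points(self):
        center, diam = min_enclosing_circle([(0.0, 0.0), (6.0, 8.0)])
        assert diam == pytest.approx(10.0)
        assert center == pytest.approx((3.0, 4.0))

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            min_enclosing_circle([])

    def test_all_points_enclosed(self, rng):
        pts = rng.random((200, 2)) * 50
        center, diam = min_enclosing_circle(pts)
        d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        assert np.all(d <= diam / 2 + 1e-9)

    @pytest.mark.parametrize("n", [3, 5, 12, 25, 30])
    def test_matches_brute_force(self, n, rng):
        for _ in range(10):
            pts = rng.random((n, 2)) * 100 - 50
            c, diam = min_enclosing_circle(pts)
            bc, bdiam = brute_force_mec(pts)
            assert diam == pytest.approx(bdiam, abs=1e-6)
            assert c == pytest.approx(bc, abs=1e-6)

    def test_matches_shapely_radius(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import MultiPoint

        for _ in range(20):
            pts = rng.random((40, 2)) * 100
            _, diam = min_enclosing_circle(pts)
            ref = 2 * shapely.minimum_bounding_radius(MultiPoint(pts.tolist()))
            assert diam == pytest.approx(ref, abs=1e-6)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_permutation_translation_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((15, 2)) * 10
        _, diam = min_enclosing_circle(pts)
        _, diam_perm = min_enclosing_circle(pts[rng.permutation(15)])
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        _, diam_moved = min_enclosing_circle(pts @ rot.T + rng.uniform(-5, 5, 2))
        assert diam_perm == pytest.approx(diam, abs=1e-9)
        assert diam_moved == pytest.approx(diam, abs=1e-7)

    def test_collinear_points(self):
        pts = [(float(i), 2.0 * i) for i in range(10)]
        _, diam = min_enclosing_circle(pts)
        assert diam == pytest.approx(math.hypot(9.0, 18.0), abs=1e-9)


class TestClassifyAndSummarize:
    @staticmethod
    def terr(d, border=False):
        return Territory(0, 10, (0.0, 0.0), d, touches_border=border)

    def test_all_below_cutoff(self):
        s = classify_and_summarize([self.terr(50.0)] * 4, cutoff=70.0)
        assert s.pct_above_cutoff == 0.0
        assert s.mean_diameter_above_cutoff is None

    def test_hand_counted_mixture(self):
        s = classify_and_summarize([self.terr(d) for d in (60.0, 80.0, 100.0)], cutoff=70.0)
        assert s.pct_above_cutoff == pytest.approx(100 * 2 / 3)
        assert s.mean_diameter_above_cutoff == pytest.approx(90.0)

    def test_cutoff_is_strict(self):
        s = classify_and_summarize([self.terr(70.0), self.terr(71.0)], cutoff=70.0)
        assert s.pct_above_cutoff == pytest.approx(50.0)

    def test_border_cells_excluded_by_default(self):
        terrs = [self.terr(100.0, border=True), self.terr(50.0)]
        s = classify_and_summarize(terrs, cutoff=70.0)
        assert s.n_cells == 1
        assert s.pct_above_cutoff == 0.0
        s_inc = classify_and_summarize(terrs, cutoff=70.0, include_border=True)
        assert s_inc.n_cells == 2

    def test_empty_rejected(self):
        with pytest.raises(UndefinedSummaryError):
            classify_and_summarize([], cutoff=70.0)


class TestMeasureTerritories:
    def test_disk_diameter_recovered(self):
        img = np.zeros((100, 100))
        yy, xx = np.mgrid[0:100, 0:100]
        img[(yy - 50) ** 2 + (xx - 50) ** 2 <= 20**2] = 100
        terrs = measure_territories(FieldImage(img, pixel_size=2.0), 50.0)
        assert len(terrs) == 1
        # 40 px diameter disk at 2 um/px -> 80 um, within one pixel width
        assert terrs[0].circle_diameter == pytest.approx(80.0, abs=2.0)
        assert not terrs[0].touches_border

    def test_border_cell_flagged(self):
        img = np.zeros((30, 30))
        img[0:8, 0:8] = 100
        terrs = measure_territories(FieldImage(img, 1.0), 50.0, min_pixels=4)
        assert terrs[0].touches_border
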