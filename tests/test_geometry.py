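"""Contour, hull, extent, centroid and RHC of binary silhouettes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertphen import (
    PlantMask,
    analyze_mask,
    compute_centroid,
    compute_rhc,
    contour_perimeter,
    convex_hull,
    extract_contour,
    plant_extent,
)
from vertphen.geometry import GeometryError

from conftest import random_blob_mask


def rect_mask(shape, r0, r1, c0, c1):
    pix = np.zeros(shape, dtype=bool)
    pix[r0:r1, c0:c1] = True
    return PlantMask(pix)


def boundary_pixel_set(pix):
    """Oracle: foreground pixels with at least one background 4-neighbour."""
    padded = np.pad(pix, 1)
    inner = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return pix & ~inner


class TestContour:
    def test_filled_square_has_36_boundary_pixels(self):
        mask = rect_mask((20, 20), 5, 15, 5, 15)
        contour = extract_contour(mask)
        assert len(contour) == 36
        assert contour_perimeter(contour) == pytest.approx(36.0)

    def test_single_pixel_contour(self):
        pix = np.zeros((5, 5), dtype=bool)
        pix[2, 3] = True
        contour = extract_contour(PlantMask(pix))
        assert contour.tolist() == [[3, 2]]
        assert contour_perimeter(contour) == 1.0

    def test_largest_component_only(self):
        pix = np.zeros((30, 30), dtype=bool)
        pix[2:5, 2:5] = True          # 9 px
        pix[10:25, 10:25] = True      # 225 px
        contour = extract_contour(PlantMask(pix))
        assert contour[:, 0].min() >= 10 and contour[:, 1].min() >= 10

    def test_traces_exactly_the_boundary_pixels(self, rng):
        from scipy.ndimage import binary_fill_holes

        mask = random_blob_mask(rng)
        contour = extract_contour(mask)
        traced = set(map(tuple, contour))
        # oracle restricted to the outer boundary: fill interior holes first
        expect = boundary_pixel_set(binary_fill_holes(mask.pixels))
        expected = {(c, r) for r, c in zip(*np.nonzero(expect))}
        assert expected <= traced

    def test_empty_mask_rejected(self):
        with pytest.raises(GeometryError):
            extract_contour(PlantMask(np.zeros((4, 4), bool)))


class TestConvexHull:
    def test_square_corners(self):
        pts = np.array([[c, r] for r in range(4) for c in range(4)])
        hull = convex_hull(pts)
        assert sorted(map(tuple, hull)) == [(0, 0), (0, 3), (3, 0), (3, 3)]

    def test_collinear_degenerates_to_two_points(self):
        pts = np.array([[i, 2 * i] for i in range(5)])
        hull = convex_hull(pts)
        assert len(hull) == 2
        assert {tuple(p) for p in hull} == {(0.0, 0.0), (4.0, 8.0)}

    def test_every_point_inside_hull(self, rng):
        pts = rng.normal(size=(200, 2)) * 10
        hull = convex_hull(pts)
        # containment oracle: each point is left of every CCW hull edge
        for p in pts:
            for i in range(len(hull)):
                a, b = hull[i], hull[(i + 1) % len(hull)]
                cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                assert cross >= -1e-9


class TestExtent:
    def test_full_bar_no_filtering(self):
        mask = rect_mask((200, 50), 10, 110, 0, 50)
        assert plant_extent(mask, 0.0) == (10, 109, 99)

    def test_droop_tail_excluded(self):
        pix = np.zeros((200, 100), dtype=bool)
        pix[10:110, :] = True                 # 10000 px bar
        pix[110:151, 50] = True               # 41-px drooping tail (<0.5%)
        top, bottom, ph = plant_extent(PlantMask(pix), 0.005)
        assert (top, bottom, ph) == (10, 109, 99)
        # oracle: explicit row-histogram quantile
        rows = np.sort(np.nonzero(pix)[0])
        assert rows[int(np.ceil(0.995 * rows.size)) - 1] == 109

    def test_zero_quantile_is_min_max(self, rng):
        mask = random_blob_mask(rng)
        rows = np.nonzero(mask.pixels)[0]
        assert plant_extent(mask, 0.0)[:2] == (rows.min(), rows.max())

    def test_single_row_rejected(self):
        with pytest.raises(GeometryError):
            plant_extent(rect_mask((10, 10), 4, 5, 0, 10), 0.0)


class TestCentroidAndRHC:
    def test_rectangle_centroid_by_symmetry(self):
        mask = rect_mask((20, 30), 0, 10, 0, 20)
        assert compute_centroid(mask) == pytest.approx((9.5, 4.5))

    def test_two_pixel_midpoint(self):
        pix = np.zeros((20, 5), dtype=bool)
        pix[0, 2] = pix[10, 2] = True
        assert compute_centroid(PlantMask(pix))[1] == pytest.approx(5.0)

    def test_centroid_matches_bruteforce(self, rng):
        mask = random_blob_mask(rng)
        col, row = compute_centroid(mask)
        rows, cols = np.nonzero(mask.pixels)
        assert col == pytest.approx(cols.mean(), abs=1e-9)
        assert row == pytest.approx(rows.mean(), abs=1e-9)

    def test_uniform_rectangle_rhc_is_half(self):
        mask = rect_mask((100, 20), 10, 90, 0, 20)
        extent = plant_extent(mask, 0.0)[:2]
        assert compute_rhc(mask, extent) == pytest.approx(0.5)

    def test_top_strip_rhc(self):
        # mass uniform in the top 10% of a 200-row extent -> ~0.95
        pix = np.zeros((220, 30), dtype=bool)
        pix[0:20, :] = True
        rhc = compute_rhc(PlantMask(pix), (0, 199))
        assert abs(rhc - 0.95) <= 1.0 / 200

    def test_rhc_matches_bruteforce(self, rng):
        for _ in range(5):
            mask = random_blob_mask(rng)
            top, bottom, _ = plant_extent(mask, 0.0)
            rows = np.nonzero(mask.pixels)[0]
            oracle = np.mean((bottom - rows) / (bottom - top))
            assert compute_rhc(mask, (top, bottom)) == pytest.approx(
                oracle, abs=1e-9
            )


class TestRHCInvariants:
    @given(dc=st.integers(0, 20), mirror=st.booleans())
    @settings(max_examples=20, deadline=None)
    def test_translation_and_mirror_invariance(self, dc, mirror):
        rng = np.random.default_rng(11)
        mask = random_blob_mask(rng, shape=(60, 40))
        pix = np.zeros((60, 80), dtype=bool)
        pix[:, dc:dc + 40] = mask.pixels[:, ::-1] if mirror else mask.pixels
        moved = PlantMask(pix)
        e1 = plant_extent(mask, 0.0)[:2]
        e2 = plant_extent(moved, 0.0)[:2]
        assert compute_rhc(moved, e2) == pytest.approx(
            compute_rhc(mask, e1), abs=1e-12
        )

    def test_uniform_rescale_invariance(self, rng):
        mask = random_blob_mask(rng)
        big = PlantMask(np.kron(mask.pixels, np.ones((2, 2), dtype=bool)))
        e1, e2 = plant_extent(mask, 0.0), plant_extent(big, 0.0)
        r1 = compute_rhc(mask, e1[:2])
        r2 = compute_rhc(big, e2[:2])
        assert abs(r1 - r2) <= 2.0 / e1[2]

    def test_moving_mass_up_increases_rhc(self, rng):
        mask = random_blob_mask(rng)
        top, bottom, _ = plant_extent(mask, 0.0)
        base = compute_rhc(mask, (top, bottom))
        # move one interior foreground pixel strictly upward
        rows, cols = np.nonzero(mask.pixels)
        for r, c in zip(rows, cols):
            if r - 1 > top and not mask.pixels[r - 1, c] and r < bottom:
                moved = mask.pixels.copy()
                moved[r, c] = False
                moved[r - 1, c] = True
                assert compute_rhc(PlantMask(moved), (top, bottom)) >= base
                return
        pytest.skip("no movable pixel in blob")

    def test_rhc_in_open_unit_interval(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng, shape=(50, 30))
            top, bottom, _ = plant_extent(mask, 0.0)
            assert 0.0 < compute_rhc(mask, (top, bottom)) < 1.0

    def test_centroid_inside_hull(self, rng):
        mask = random_blob_mask(rng)
        geom = analyze_mask(mask, droop_quantile=0.0)
        cx, cy = geom.centroid
        hull = geom.hull
        for i in range(len(hull)):
            a, b = hull[i], hull[(i + 1) % len(hull)]
            cross = (b[0] - a[0]) * (cy - a[1]) - (b[1] - a[1]) * (cx - a[0])
            assert cross >= -1e-9
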