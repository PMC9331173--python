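"""Edge/skeleton line sources, Hough leaf segments, angles and heights."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import line as draw_line

from vertphen import (
    HoughParams,
    PlantMask,
    SyntheticPlantSpec,
    detect_edges,
    detect_leaf_lines,
    generate_plant,
    mask_from_truth,
    relative_height,
    segment_angle,
    skeletonize_plant,
)
from vertphen.geometry import analyze_mask
from vertphen.leaflines import LeafLineError


def stroke_raster(angle_deg, length=100, shape=(240, 240), origin=(200, 20)):
    img = np.zeros(shape, dtype=bool)
    r0, c0 = origin
    dr = -length * math.sin(math.radians(angle_deg))
    dc = length * math.cos(math.radians(angle_deg))
    rr, cc = draw_line(r0, c0, int(round(r0 + dr)), int(round(c0 + dc)))
    img[rr, cc] = True
    return img


class TestSegmentAngle:
    @pytest.mark.parametrize(
        "p1,p2,expect",
        [((0, 0), (10, 0), 0.0), ((0, 0), (0, 10), 90.0), ((0, 0), (10, 10), 45.0)],
    )
    def test_cardinal_angles(self, p1, p2, expect):
        assert segment_angle(p1, p2) == pytest.approx(expect)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(LeafLineError):
            segment_angle((3, 3), (3, 3))

    @given(
        x1=st.integers(-50, 50), y1=st.integers(-50, 50),
        x2=st.integers(-50, 50), y2=st.integers(-50, 50),
        scale=st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_scale_and_mirror_invariance(self, x1, y1, x2, y2, scale):
        if (x1, y1) == (x2, y2):
            return
        a = segment_angle((x1, y1), (x2, y2))
        assert 0.0 <= a <= 90.0
        assert segment_angle((x2, y2), (x1, y1)) == pytest.approx(a)
        assert segment_angle(
            (x1 * scale, y1 * scale), (x2 * scale, y2 * scale)
        ) == pytest.approx(a)
        assert segment_angle((-x1, y1), (-x2, y2)) == pytest.approx(a)


class TestRelativeHeight:
    @pytest.mark.parametrize(
        "row,expect", [(100, 0.0), (0, 100.0), (50, 50.0)]
    )
    def test_linear_scale(self, row, expect):
        assert relative_height(row, (0, 100)) == pytest.approx(expect)

    def test_clipping(self):
        assert relative_height(150, (0, 100)) == 0.0
        assert relative_height(-20, (0, 100)) == 100.0

    def test_zero_height_rejected(self):
        with pytest.raises(LeafLineError):
            relative_height(5, (10, 10))


class TestLineSources:
    def test_rectangle_edges_trace_sides(self):
        pix = np.zeros((40, 40), dtype=bool)
        pix[10:30, 10:30] = True
        edges = detect_edges(PlantMask(pix))
        # distance-transform oracle: every edge pixel within 2 px of boundary
        from scipy.ndimage import distance_transform_edt

        from test_geometry import boundary_pixel_set

        dist = distance_transform_edt(~boundary_pixel_set(pix))
        assert edges.any()
        assert dist[edges].max() <= 2.0

    def test_edges_on_empty_mask_rejected(self):
        with pytest.raises(LeafLineError):
            detect_edges(PlantMask(np.zeros((5, 5), bool)))

    def test_bar_skeleton_is_midline(self):
        pix = np.zeros((20, 60), dtype=bool)
        pix[8:13, 5:55] = True
        skel = skeletonize_plant(PlantMask(pix))
        rows, cols = np.nonzero(skel)
        interior = (cols >= 10) & (cols <= 50)
        assert interior.any()
        assert set(rows[interior]) == {10}  # endpoints may wobble 1 px

    def test_single_pixel_skeleton(self):
        pix = np.zeros((5, 5), dtype=bool)
        pix[2, 2] = True
        assert np.array_equal(skeletonize_plant(PlantMask(pix)), pix)

    def test_skeleton_subset_of_mask(self, default_plant):
        _, truth = default_plant
        mask = mask_from_truth(truth)
        skel = skeletonize_plant(mask)
        assert not (skel & ~mask.pixels).any()

    def test_plus_shape_contains_axes(self):
        pix = np.zeros((31, 31), dtype=bool)
        pix[14:17, 3:28] = True
        pix[3:28, 14:17] = True
        skel = skeletonize_plant(PlantMask(pix))
        assert skel[15, 8] and skel[15, 22] and skel[8, 15] and skel[22, 15]


class TestDetectLeafLines:
    def test_single_stroke_angle_recovered(self):
        raster = stroke_raster(30.0)
        segs = detect_leaf_lines(
            raster, HoughParams(stem_filter=False), (0, 239), seed=0
        )
        assert len(segs) == 1
        assert abs(segs[0].angle_deg - 30.0) <= 2.0

    def test_blank_raster_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            segs = detect_leaf_lines(
                np.zeros((50, 50), bool), HoughParams(), (0, 49), seed=0
            )
        assert segs == []

    def test_parallel_strokes_not_merged(self):
        raster = stroke_raster(45.0, origin=(200, 20))
        raster |= stroke_raster(45.0, origin=(200, 80))
        segs = detect_leaf_lines(
            raster, HoughParams(stem_filter=False), (0, 239), seed=0
        )
        assert len(segs) == 2

    def test_sparse_plant_recovery_rate(self):
        # >=80% of strokes recovered with angle error <=3 deg and relative
        # height error <=3 points, on plants sparse enough that strokes do
        # not occlude each other
        for seed in (0, 1):
            image, truth = generate_plant(
                SyntheticPlantSpec(n_leaves=12, seed=seed)
            )
            mask = mask_from_truth(truth)
            geom = analyze_mask(mask, droop_quantile=0.0)
            segs = detect_leaf_lines(
                skeletonize_plant(mask), HoughParams(), geom, seed=0
            )
            hits = 0
            for leaf in truth.leaves:
                for s in segs:
                    close = math.hypot(
                        s.midpoint[0] - leaf.midpoint[0],
                        s.midpoint[1] - leaf.midpoint[1],
                    ) < 15
                    if (
                        close
                        and abs(s.angle_deg - leaf.angle_deg) <= 3.0
                        and abs(s.rel_height - leaf.rel_height) <= 3.0
                    ):
                        hits += 1
                        break
            assert hits >= 0.8 * len(truth.leaves)

    def test_segment_fields_in_range(self, default_plant):
        _, truth = default_plant
        mask = mask_from_truth(truth)
        geom = analyze_mask(mask, droop_quantile=0.0)
        segs = detect_leaf_lines(
            skeletonize_plant(mask), HoughParams(), geom, seed=0
        )
        assert segs
        for s in segs:
            assert 0.0 <= s.angle_deg <= 90.0
            assert 0.0 <= s.rel_height <= 100.0
            assert s.length_px > 0
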