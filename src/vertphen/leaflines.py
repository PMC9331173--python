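"""Leaf line-segment extraction: edges/skeleton + probabilistic Hough.

Rice leaves in a front-view silhouette are well approximated by straight
elongated strokes.  The silhouette is reduced to a 1-px line drawing (medial
axis skeleton by default, Canny edges as an option) and the probabilistic
Hough transform turns it into line segments.  Each segment carries

* its inclination angle A_l from the horizontal, folded to [0, 90] degrees —
  leaves leaning left or right are equivalent, and
* its relative height RH_l = 100 * (bottom_row - midpoint_row) / PH, the
  midpoint height above the plant bottom as a percent of plant height.

The (A_l, RH_l) pairs are the data the vertical leaf-angle distribution
model is fitted to.

The probabilistic Hough transform fragments single leaves into several
near-collinear detections; segments closer than a few degrees and a few
pixels are merged into one longest-span representative before fitting (the
merge can be disabled).  Long near-horizontal segments are discarded as
pot-rim/ground artifacts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.morphology import skeletonize
from skimage.transform import probabilistic_hough_line

from .segmentation import PlantMask

Point = tuple[float, float]


class LeafLineError(ValueError):
    pass


@dataclass(frozen=True)
class HoughParams:
    """Probabilistic Hough transform settings.

    ``min_line_length=None`` ties the length floor to plant size
    (0.05 * PH) rather than image size.
    """

    threshold: int = 20
    min_line_length: int | None = None
    max_line_gap: int = 5
    rho_res: float = 1.0
    theta_res_deg: float = 1.0
    merge_segments: bool = True
    merge_angle_deg: float = 5.0
    merge_dist_px: float = 3.0
    merge_gap_px: float = 10.0      # max along-line gap between fragments
    stem_filter: bool = True        # drop long near-vertical stem detections
    stem_angle_deg: float = 88.0
    stem_length_frac: float = 0.4   # of plant height
    prune_junctions: bool = False   # cut skeleton branch points before Hough
    junction_radius_px: int = 2


@dataclass
class LeafSegment:
    """One detected leaf line with its angle and relative height."""

    p1: Point
    p2: Point
    midpoint: Point
    length_px: float
    angle_deg: float      # inclination from horizontal, [0, 90]
    rel_height: float     # percent of plant height, [0, 100]


def segment_angle(p1: Point, p2: Point) -> float:
    """Unsigned inclination of the segment from the horizontal, degrees.

    angle = atan(|d_row| / |d_col|), folded to [0, 90]; vertical segments
    give 90.  Independent of endpoint order and of horizontal mirroring.
    """
    dcol = p2[0] - p1[0]
    drow = p2[1] - p1[1]
    if dcol == 0 and drow == 0:
        raise LeafLineError("coincident endpoints have no angle")
    return math.degrees(math.atan2(abs(drow), abs(dcol)))


def relative_height(midpoint_row: float, extent: tuple[int, int]) -> float:
    """Midpoint height above the plant bottom as percent of plant height.

    100 * (bottom_row - midpoint_row) / (bottom_row - top_row), clipped to
    [0, 100] (segments protruding past the droop-filtered extent saturate).
    """
    top_row, bottom_row = extent
    if bottom_row <= top_row:
        raise LeafLineError("zero plant height")
    rh = 100.0 * (bottom_row - midpoint_row) / (bottom_row - top_row)
    return float(min(100.0, max(0.0, rh)))


def detect_edges(
    mask: PlantMask, low_thr: float = 0.1, high_thr: float = 0.2, sigma: float = 1.0
) -> np.ndarray:
    """Canny edge raster of the (smoothed) plant mask."""
    if mask.empty:
        raise LeafLineError("cannot detect edges on an empty mask")
    return canny(
        mask.pixels.astype(float),
        sigma=sigma,
        low_threshold=low_thr,
        high_threshold=high_thr,
    )


def skeletonize_plant(mask: PlantMask) -> np.ndarray:
    """1-px-wide medial-axis raster of the plant silhouette.

    A subset of the mask; preserves the connectivity of each component.
    """
    return skeletonize(mask.pixels)


def _prune_junctions(skeleton: np.ndarray, radius: int) -> np.ndarray:
    """Remove branch points (and a small neighbourhood) from a 1-px raster.

    Where a leaf skeleton meets the culm or crosses another leaf, the
    medial axis bends; the pixels around such junctions carry the wrong
    local direction and bias line angles.  Cutting them leaves clean
    straight branches that the Hough stage re-reads individually.
    """
    from scipy.ndimage import convolve

    sk = np.asarray(skeleton, dtype=bool)
    neighbours = convolve(sk.astype(np.uint8), np.ones((3, 3), np.uint8),
                          mode="constant") - sk
    junctions = sk & (neighbours >= 3)
    if not junctions.any():
        return sk
    from skimage.morphology import dilation, disk

    return sk & ~dilation(junctions, disk(radius))


def _point_line_distance(p: np.ndarray, a: np.ndarray, u: np.ndarray) -> float:
    """Perpendicular distance of p from the infinite line through a along unit u."""
    w = p - a
    return float(abs(w[0] * u[1] - w[1] * u[0]))


def _merge_cluster(segs: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Longest-span representative: extreme endpoint projections onto the
    direction of the cluster's longest member."""
    lengths = [float(np.linalg.norm(b - a)) for a, b in segs]
    a0, b0 = segs[int(np.argmax(lengths))]
    u = (b0 - a0) / np.linalg.norm(b0 - a0)
    pts = np.array([p for seg in segs for p in seg], dtype=float)
    proj = (pts - a0) @ u
    return pts[int(proj.argmin())], pts[int(proj.argmax())]


def detect_leaf_lines(
    line_source: np.ndarray,
    hough: HoughParams,
    geometry,
    seed: int = 0,
) -> list[LeafSegment]:
    """Detect leaf segments in an edge or skeleton raster.

    Parameters
    ----------
    line_source : 2-D bool array
        Edge or skeleton raster of the plant.
    hough : HoughParams
        Transform settings; ``min_line_length=None`` defaults to 5% of the
        plant height.
    geometry : PlantGeometry or (top_row, bottom_row)
        Plant geometry: the droop-filtered extent drives relative heights
        and the default length floor; when the full geometry is given, its
        centroid column locates the culm axis for the stem filter.
    seed : int
        Seeds the probabilistic Hough sampling; fixed seed gives fixed output.

    Returns an empty list (with a warning) when nothing is found, so the
    caller can refuse to fit rather than crash.
    """
    src = np.asarray(line_source, dtype=bool)
    if src.size == 0 or src.ndim != 2:
        raise LeafLineError("line source must be a nonempty 2-D raster")
    if isinstance(geometry, tuple):
        top_row, bottom_row = geometry
        centroid_col = None
    else:
        top_row, bottom_row = geometry.top_row, geometry.bottom_row
        centroid_col = geometry.centroid[0]
    ph = bottom_row - top_row
    min_len = hough.min_line_length
    if min_len is None:
        min_len = max(5, round(0.05 * ph))
    if hough.prune_junctions:
        src = _prune_junctions(src, hough.junction_radius_px)
    theta = np.deg2rad(
        np.arange(-90.0, 90.0, hough.theta_res_deg, dtype=float)
    )
    raw = probabilistic_hough_line(
        src,
        threshold=hough.threshold,
        line_length=int(min_len),
        line_gap=int(hough.max_line_gap),
        theta=theta,
        rng=np.random.default_rng(seed),
    )
    segs = [
        (np.array(p1, dtype=float), np.array(p2, dtype=float)) for p1, p2 in raw
    ]
    if hough.merge_segments and len(segs) > 1:
        segs = _merge_near_collinear(
            segs, hough.merge_angle_deg, hough.merge_dist_px, hough.merge_gap_px
        )

    # scene-furniture filters, applied after merging so fragments of the same
    # structure are judged by their full span: very long near-horizontal lines
    # are pot rim / ground; near-vertical lines are the culm when they either
    # span a large fraction of the plant or sit on the culm axis (the
    # silhouette centroid column)
    width = src.shape[1]
    kept = []
    for a, b in segs:
        length = float(np.linalg.norm(b - a))
        ang = segment_angle(tuple(a), tuple(b))
        if ang < 2.0 and length > 0.5 * width:
            continue
        if hough.stem_filter and ang > hough.stem_angle_deg:
            mid_col = (a[0] + b[0]) / 2.0
            on_axis = (
                centroid_col is not None
                and abs(mid_col - centroid_col) <= hough.merge_dist_px
            )
            if length > hough.stem_length_frac * ph or on_axis:
                continue
        kept.append((a, b))
    segs = kept

    out: list[LeafSegment] = []
    for a, b in segs:
        mid = (a + b) / 2.0
        out.append(
            LeafSegment(
                p1=(float(a[0]), float(a[1])),
                p2=(float(b[0]), float(b[1])),
                midpoint=(float(mid[0]), float(mid[1])),
                length_px=float(np.linalg.norm(b - a)),
                angle_deg=segment_angle(tuple(a), tuple(b)),
                rel_height=relative_height(float(mid[1]), (top_row, bottom_row)),
            )
        )
    if not out:
        warnings.warn("no leaf line segments detected", stacklevel=2)
    return out


def _merge_near_collinear(
    segs: list[tuple[np.ndarray, np.ndarray]],
    max_angle_deg: float,
    max_dist_px: float,
    max_gap_px: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Greedy clustering of fragments of the same leaf.

    A segment joins the cluster of the longest compatible representative
    when (i) inclinations differ by <= ``max_angle_deg``, (ii) its midpoint
    lies within ``max_dist_px`` of the representative's carrier line, and
    (iii) its projection onto that line overlaps the cluster's span or falls
    within ``max_gap_px`` of it — distinct collinear leaves further apart
    along the line stay separate.  Each cluster is replaced by its
    longest-span representative.
    """
    order = sorted(
        range(len(segs)), key=lambda i: -np.linalg.norm(segs[i][1] - segs[i][0])
    )
    clusters: list[list[tuple[np.ndarray, np.ndarray]]] = []
    # (anchor, unit direction, angle, projected span [lo, hi])
    reps: list[list] = []
    for i in order:
        a, b = segs[i]
        ang = segment_angle(tuple(a), tuple(b))
        mid = (a + b) / 2.0
        placed = False
        for ci, (ra, ru, rang, span) in enumerate(reps):
            dang = abs(ang - rang)
            dang = min(dang, 180.0 - dang)
            if dang > max_angle_deg:
                continue
            if _point_line_distance(mid, ra, ru) > max_dist_px:
                continue
            lo = float(min((a - ra) @ ru, (b - ra) @ ru))
            hi = float(max((a - ra) @ ru, (b - ra) @ ru))
            if lo > span[1] + max_gap_px or hi < span[0] - max_gap_px:
                continue  # collinear but disjoint: a different leaf
            clusters[ci].append((a, b))
            span[0], span[1] = min(span[0], lo), max(span[1], hi)
            placed = True
            break
        if not placed:
            u = (b - a) / np.linalg.norm(b - a)
            span = sorted([0.0, float((b - a) @ u)])
            reps.append([a, u, ang, span])
            clusters.append([(a, b)])
    return [_merge_cluster(c) for c in clusters]
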