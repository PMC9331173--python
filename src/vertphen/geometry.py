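"""Silhouette geometry: contour, hull, extent, centroid and RHC.

The relative height of the plant centroid,

    RHC = Centroid Height / Plant Height,

locates the plant's growth focus: both quantities are measured in pixels on
the front-view silhouette, heights upward from the plant's bottommost row.
Rasters use a top-origin row convention; that convention is inverted exactly
once, here, so every height downstream of this module is "pixels above the
bottom row".

Plant height is robust to drooping leaf tips: the top and bottom rows are
quantiles of the foreground row distribution (``droop_quantile`` at each end),
with 0 disabling the filter.  Pixels outside the filtered extent are excluded
from the moment sums, keeping 0 < RHC < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .segmentation import PlantMask

SQRT2 = float(np.sqrt(2.0))


class GeometryError(ValueError):
    """Raised when a geometric quantity is undefined for the given mask."""


@dataclass
class PlantGeometry:
    """Silhouette geometry of one plant image.

    Coordinates are (col, row) raster pairs.  ``plant_height_px`` is the
    droop-filtered vertical extent (PH); ``centroid_height_px`` is the
    centroid's height above ``bottom_row``; ``rhc`` their ratio.
    """

    contour: np.ndarray            # (n, 2) ordered closed boundary, (col,row)
    hull: np.ndarray               # (h, 2) convex polygon vertices, CCW
    top_row: int
    bottom_row: int
    plant_height_px: int
    centroid: tuple[float, float]  # (col, row)
    centroid_height_px: float
    rhc: float
    area_px: int
    perimeter_px: float
    hole_perimeter_px: float = 0.0  # arc length of inner hole boundaries
    warnings: list[str] = field(default_factory=list)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from skimage.measure import label

    labels, n = label(mask, connectivity=2, return_num=True)
    if n <= 1:
        return mask
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return labels == int(areas.argmax())


# Moore neighbourhood in clockwise order starting east, (drow, dcol).
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def extract_contour(mask: PlantMask) -> np.ndarray:
    """Trace the outer boundary of the largest connected component.

    Returns an ordered closed polyline of (col, row) pixel coordinates,
    produced by Moore-neighbour tracing with Jacob's stopping criterion
    (the trace ends when the start pixel is re-entered by the same move that
    began it).  A single-pixel mask yields a one-point contour (perimeter
    defined as 1).
    """
    if mask.empty:
        raise GeometryError("cannot extract a contour from an empty mask")
    pix = _largest_component(mask.pixels)
    rows, cols = np.nonzero(pix)
    if rows.size == 1:
        return np.array([[cols[0], rows[0]]])

    padded = np.zeros((pix.shape[0] + 2, pix.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = pix
    # Uppermost-leftmost foreground pixel: its west neighbour is background.
    start = (int(rows.min()) + 1, int(cols[rows == rows.min()].min()) + 1)
    boundary: list[tuple[int, int]] = [start]
    cur = start
    back = 4  # index of a known-background neighbour (west of start)
    first_move: int | None = None
    while True:
        for k in range(1, 9):
            d = (back + k) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if padded[nxt]:
                break
        else:  # isolated pixel; cannot happen for >1-pixel components
            break
        if cur == start:
            if first_move is None:
                first_move = d
            elif d == first_move:
                break  # closed: about to repeat the opening move
        # new backtrack: direction from nxt to the last background neighbour
        # scanned (consecutive ring positions always differ by a king move)
        prev_bg = (cur[0] + _MOORE[(d - 1) % 8][0],
                   cur[1] + _MOORE[(d - 1) % 8][1])
        back = _MOORE.index((prev_bg[0] - nxt[0], prev_bg[1] - nxt[1]))
        boundary.append(nxt)
        cur = nxt
    if len(boundary) > 1 and boundary[-1] == start:
        boundary.pop()
    pts = np.array(boundary)
    return np.column_stack([pts[:, 1] - 1, pts[:, 0] - 1])  # (col, row)


def contour_perimeter(contour: np.ndarray) -> float:
    """Arc length of a closed contour under the 8-connected metric.

    Axis steps count 1, diagonal steps sqrt(2) (Euclidean step lengths); the
    closing edge from the last point back to the first is included.  A
    single-point contour has perimeter 1 by convention (one isolated pixel).
    """
    if len(contour) == 1:
        return 1.0
    closed = np.vstack([contour, contour[:1]])
    d = np.diff(closed.astype(float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Minimal convex polygon containing every input point.

    Vertices are returned in counter-clockwise order (raster coordinates).
    Degenerate inputs (single point, collinear points) yield 1- or 2-vertex
    "polygons" — the extreme points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise GeometryError("need a nonempty (n, 2) point array")
    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        return uniq
    try:
        hull = ConvexHull(uniq)
    except QhullError:
        # collinear: return the two extreme points along the spread direction
        centred = uniq - uniq.mean(axis=0)
        direction = centred[np.abs(centred).sum(axis=1).argmax()]
        proj = centred @ direction
        return uniq[[int(proj.argmin()), int(proj.argmax())]]
    return uniq[hull.vertices]


def plant_extent(
    mask: PlantMask, droop_quantile: float = 0.005
) -> tuple[int, int, int]:
    """Droop-filtered vertical extent (top_row, bottom_row, plant_height_px).

    ``top_row`` and ``bottom_row`` are the ``droop_quantile`` and
    ``1 - droop_quantile`` order statistics of the foreground row
    distribution, so sparse drooping tips (fewer than that fraction of plant
    pixels) do not stretch the measured plant height.  ``droop_quantile=0``
    gives the raw min/max rows.
    """
    if mask.empty:
        raise GeometryError("extent undefined for an empty mask")
    if not (0.0 <= droop_quantile < 0.5):
        raise GeometryError("droop_quantile must lie in [0, 0.5)")
    rows = np.sort(np.nonzero(mask.pixels)[0])
    n = rows.size
    lo = int(np.floor(droop_quantile * n))
    hi = int(np.ceil((1.0 - droop_quantile) * n)) - 1
    top_row, bottom_row = int(rows[lo]), int(rows[hi])
    if bottom_row == top_row:
        raise GeometryError("mask spans a single row; plant height undefined")
    return top_row, bottom_row, bottom_row - top_row


def compute_centroid(mask: PlantMask) -> tuple[float, float]:
    """Silhouette centroid (col, row): first-order moments of the binary mask.

    Equal weight per foreground pixel — the arithmetic mean of pixel
    coordinates (M10/M00, M01/M00).
    """
    if mask.empty:
        raise GeometryError("centroid undefined for an empty mask")
    rows, cols = np.nonzero(mask.pixels)
    return float(cols.mean()), float(rows.mean())


def compute_rhc(mask: PlantMask, extent: tuple[int, int]) -> float:
    """Relative height of the plant centroid.

    RHC = (bottom_row - centroid_row) / (bottom_row - top_row), with the
    centroid taken over foreground pixels inside [top_row, bottom_row] only,
    so droop-filtered pixels cannot push RHC outside (0, 1).
    """
    top_row, bottom_row = extent
    if bottom_row <= top_row:
        raise GeometryError("zero plant height")
    rows = np.nonzero(mask.pixels)[0]
    rows = rows[(rows >= top_row) & (rows <= bottom_row)]
    if rows.size == 0:
        raise GeometryError("no foreground pixels inside the extent")
    return float((bottom_row - rows.mean()) / (bottom_row - top_row))


def _hole_perimeter(mask: np.ndarray) -> float:
    """Total arc length of inner hole boundaries of the largest component.

    Tiller gaps enclosed by the silhouette contribute boundary length that
    the compactness descriptor PAR counts alongside the outer contour.
    """
    from scipy.ndimage import binary_fill_holes
    from skimage.measure import label

    comp = _largest_component(mask)
    holes = binary_fill_holes(comp) & ~comp
    if not holes.any():
        return 0.0
    total = 0.0
    labels, n = label(holes, connectivity=1, return_num=True)
    for i in range(1, n + 1):
        total += contour_perimeter(extract_contour(PlantMask(labels == i)))
    return total


def analyze_mask(mask: PlantMask, droop_quantile: float = 0.005) -> PlantGeometry:
    """Full geometric analysis of one plant mask.

    Bundles contour, hull, droop-filtered extent, centroid, plant height,
    centroid height and RHC into a :class:`PlantGeometry`.
    """
    top_row, bottom_row, ph = plant_extent(mask, droop_quantile)
    contour = extract_contour(mask)
    hull = convex_hull(contour)
    centroid = compute_centroid(mask)
    rhc = compute_rhc(mask, (top_row, bottom_row))
    return PlantGeometry(
        contour=contour,
        hull=hull,
        top_row=top_row,
        bottom_row=bottom_row,
        plant_height_px=ph,
        centroid=centroid,
        centroid_height_px=rhc * ph,
        rhc=rhc,
        area_px=mask.area_px,
        perimeter_px=contour_perimeter(contour),
        hole_perimeter_px=_hole_perimeter(mask.pixels),
    )
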