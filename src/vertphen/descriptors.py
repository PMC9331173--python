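"""Projected-shape descriptors: greenness ratio (GPAR) and compactness (PAR).

GPAR — greenness projected plant area ratio — is the fraction of plant
pixels classified as green organs; it falls as leaves senesce.  PAR — the
perimeter-to-area ratio of the silhouette — indexes the compactness of the
tillers: a sprawling plant with many separated tillers has a long boundary
per unit area, a compact one a short boundary.  (This PAR is a shape
descriptor, distinct from photosynthetically active radiation.)

Both ratios are computed on projected plant pixels, not whole-image pixels,
so they are invariant to framing.  The perimeter uses the 8-connected
contour arc-length metric of :mod:`vertphen.geometry`; by default it is
normalised by the mask area, with the convex-hull area available as an
alternative denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .geometry import PlantGeometry
from .segmentation import PlantMask


class DescriptorError(ValueError):
    pass


@dataclass
class ShapeDescriptors:
    gpar: float            # fraction in [0, 1]
    par: float             # 1/pixels
    area_px: int
    green_area_px: int
    perimeter_px: float


def compute_gpar(green_mask: PlantMask, plant_mask: PlantMask) -> float:
    """Fraction of plant pixels that are green: |green| / |plant|."""
    if plant_mask.empty:
        raise DescriptorError("GPAR undefined for an empty plant mask")
    if green_mask.shape != plant_mask.shape:
        raise DescriptorError("green and plant masks must share dimensions")
    extra = green_mask.pixels & ~plant_mask.pixels
    if extra.any():
        raise DescriptorError("green mask must be a subset of the plant mask")
    return float(green_mask.area_px / plant_mask.area_px)


def _hull_area(hull: np.ndarray) -> float:
    if len(hull) < 3:
        return 0.0
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def compute_par(
    geometry: PlantGeometry,
    denominator: Literal["mask", "hull"] = "mask",
) -> float:
    """Perimeter-to-area ratio of the silhouette, in 1/pixels.

    The perimeter is the outer-contour arc length of the largest component
    plus the arc length of any inner hole boundaries (tiller gaps are part
    of the compactness signal).  ``denominator="mask"`` (default) divides by
    the foreground pixel count; ``"hull"`` divides by the convex-hull area
    instead, ignoring internal gaps between tillers.
    """
    if denominator == "mask":
        area = float(geometry.area_px)
    elif denominator == "hull":
        area = _hull_area(np.asarray(geometry.hull, dtype=float))
    else:
        raise DescriptorError(f"unknown PAR denominator {denominator!r}")
    if area <= 0:
        raise DescriptorError("PAR undefined for zero area")
    return float((geometry.perimeter_px + geometry.hole_perimeter_px) / area)


def compute_descriptors(
    green_mask: PlantMask,
    plant_mask: PlantMask,
    geometry: PlantGeometry,
    par_denominator: Literal["mask", "hull"] = "mask",
) -> ShapeDescriptors:
    return ShapeDescriptors(
        gpar=compute_gpar(green_mask, plant_mask),
        par=compute_par(geometry, par_denominator),
        area_px=plant_mask.area_px,
        green_area_px=green_mask.area_px,
        perimeter_px=geometry.perimeter_px,
    )
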