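"""Plant/background segmentation by HSV colour thresholding.

A front-view shot of a potted rice plant is separated from its background by
thresholding in HSV space: live foliage occupies a broad green hue band with
non-trivial saturation and value, while typical backgrounds (walls, soil, pot)
fall outside it.  The same machinery, with a stricter hue band, separates green
organs from senescent yellow ones for the greenness ratio (GPAR).

Conventions
-----------
* Images are ``H x W x 3`` uint8 arrays in **RGB** channel order, row 0 at the
  image top (the raster convention of PIL / scikit-image).
* Hue thresholds are stored in degrees on a 0-360 scale and converted to
  scikit-image's native 0-1 hue scale internally.
* Masks are boolean ``H x W`` arrays, True = plant.
* The default hue box does not wrap around 0 degrees; green never straddles
  the red hue origin, so wraparound is unsupported by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label
from skimage.morphology import closing, disk


class SegmentationError(ValueError):
    """Raised for invalid segmentation inputs (empty image, dim mismatch)."""


@dataclass(frozen=True)
class HSVThresholds:
    """An axis-aligned box in HSV space.

    Parameters
    ----------
    hue_lo, hue_hi : float
        Hue bounds in degrees (0-360 scale). ``hue_lo < hue_hi`` required;
        the box does not wrap around 0.
    sat_lo : float
        Minimum saturation, fraction in [0, 1].
    val_lo : float
        Minimum value (brightness), fraction in [0, 1].
    """

    hue_lo: float = 60.0
    hue_hi: float = 180.0
    sat_lo: float = 0.15
    val_lo: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_lo < self.hue_hi <= 360.0):
            raise ValueError(
                f"hue bounds must satisfy 0 <= lo < hi <= 360, got "
                f"({self.hue_lo}, {self.hue_hi})"
            )
        if not (0.0 <= self.sat_lo <= 1.0 and 0.0 <= self.val_lo <= 1.0):
            raise ValueError("sat_lo and val_lo must lie in [0, 1]")


#: Broad band for live + senescent foliage (plant vs background).
DEFAULT_PLANT_BOX = HSVThresholds(hue_lo=40.0, hue_hi=180.0)

#: Stricter band for green organs only (excludes senescent yellow, hue < 60).
DEFAULT_GREEN_BOX = HSVThresholds(hue_lo=60.0, hue_hi=180.0)


@dataclass
class PlantMask:
    """Binary plant/background raster, the substrate of all geometry.

    ``pixels`` is a boolean H x W array with the same dims as the source
    image; ``empty`` flags a mask with zero foreground pixels (a warning
    condition, not an error).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise SegmentationError("mask must be a 2-D raster")

    @property
    def empty(self) -> bool:
        return not bool(self.pixels.any())

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise SegmentationError(
            f"expected a nonempty H x W x 3 RGB image, got shape {image.shape}"
        )
    return image


def _hsv_box_mask(image: np.ndarray, thresholds: HSVThresholds) -> np.ndarray:
    hsv = rgb2hsv(image)
    hue_deg = hsv[..., 0] * 360.0
    return (
        (hue_deg >= thresholds.hue_lo)
        & (hue_deg <= thresholds.hue_hi)
        & (hsv[..., 1] >= thresholds.sat_lo)
        & (hsv[..., 2] >= thresholds.val_lo)
    )


def segment_plant(
    image: np.ndarray, thresholds: HSVThresholds = DEFAULT_PLANT_BOX
) -> PlantMask:
    """Threshold an RGB image in HSV space to isolate the plant subject.

    The mask marks exactly the pixels whose (hue, saturation, value) triple
    lies inside the threshold box.  Deterministic for fixed inputs.  A result
    with zero foreground pixels is returned with its ``empty`` flag set rather
    than raising.
    """
    image = _validate_image(image)
    return PlantMask(_hsv_box_mask(image, thresholds))


def clean_mask(
    mask: PlantMask, min_component_area: int | None = None, closing_radius: int = 2
) -> PlantMask:
    """Remove small speckle components and close thin gaps.

    Connected components (8-connectivity) smaller than ``min_component_area``
    pixels are dropped, then a morphological closing with a disk of
    ``closing_radius`` is applied.  ``min_component_area=None`` defaults to
    0.05% of the image area.  With both parameters zero this is the identity.
    An empty mask passes through unchanged.
    """
    pix = mask.pixels
    if min_component_area is None:
        min_component_area = max(1, round(0.0005 * pix.size))
    if mask.empty:
        return PlantMask(pix.copy())
    out = pix
    if min_component_area > 0:
        labels, n = label(out, connectivity=2, return_num=True)
        if n:
            areas = np.bincount(labels.ravel())
            keep = areas >= min_component_area
            keep[0] = False
            out = keep[labels]
    if closing_radius > 0:
        out = closing(out, disk(closing_radius))
    return PlantMask(out)


def green_fraction_mask(
    image: np.ndarray,
    mask: PlantMask,
    thresholds: HSVThresholds = DEFAULT_GREEN_BOX,
) -> PlantMask:
    """Subset of plant pixels classified as green organs.

    Uses a stricter hue box than :func:`segment_plant` so that senescent
    yellow organs (hue below ~60 degrees) are excluded; the result feeds the
    greenness projected-area ratio GPAR.  Always a subset of ``mask``.
    """
    image = _validate_image(image)
    if mask.shape != image.shape[:2]:
        raise SegmentationError(
            f"mask dims {mask.shape} do not match image dims {image.shape[:2]}"
        )
    return PlantMask(_hsv_box_mask(image, thresholds) & mask.pixels)
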