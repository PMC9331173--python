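"""Synthetic front-view rice plants with exact ground truth.

Real pot experiments leave no way to test an image pipeline against known
answers, so this module renders rice-like silhouettes whose every quantity
of interest is known by construction:

* leaves are straight strokes (the Hough stage models leaves as lines, so
  straight strokes give an unambiguous truth surface) placed at seeded
  relative heights, alternating left/right of a vertical stem;
* each leaf's inclination follows the logarithmic vertical distribution
  A = a_true * ln(RH + 1) + b_true plus optional Gaussian noise, folded to
  [0, 90];
* the background is uniform mid-gray (zero saturation — outside every
  green/yellow HSV box), so segmentation recovers the stroke raster
  pixel-for-pixel; a ``textured_background`` option sprinkles small green
  speckles to exercise mask cleaning;
* a configurable fraction of leaves is painted senescent yellow instead of
  green, giving a known greenness ratio.

Leaf strokes are truncated symmetrically about their midpoint so they never
leave the vertical extent spanned by the stem; with droop filtering off the
measured plant extent therefore equals the constructed one (up to the
stroke-width dilation, which widens both ends equally).  Rendering uses
integer raster operations only, so output is bit-identical across platforms
for a fixed spec and seed.

Truth semantics: per-leaf ``rel_height`` and ``angle_deg`` are the intended
(pre-rasterization) values — at zero noise they satisfy the model equation
exactly; ``p1/p2/midpoint`` are the integer endpoints actually drawn, whose
angle differs from the intended one by sub-degree rasterization error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .segmentation import PlantMask

GREEN_RGB = (0, 255, 0)       # hue 120 deg, s=1, v=1
YELLOW_RGB = (255, 234, 0)    # hue ~55 deg: senescent, outside the green box
BACKGROUND_RGB = (128, 128, 128)  # zero saturation: outside every box

LABEL_BG, LABEL_GREEN, LABEL_YELLOW = 0, 1, 2


class CanvasFitError(ValueError):
    """The requested plant cannot fit on the requested canvas."""


@dataclass(frozen=True)
class SyntheticPlantSpec:
    """Parameters of one synthetic plant render.

    Defaults emulate a mid-season pot shot: a 300 px plant on a 480x420
    canvas, 30 leaves of moderate length, angle noise of 3 degrees about the
    logarithmic curve with mid-range parameters (a=10, b=30), all organs
    green.
    """

    a_true: float = 10.0
    b_true: float = 30.0
    n_leaves: int = 30
    plant_height_px: int = 300
    stroke_width_px: int = 3
    leaf_length_px: int = 90
    angle_noise_sd_deg: float = 3.0
    green_fraction: float = 1.0
    stem: bool = True
    canvas: tuple[int, int] = (480, 420)   # (H, W)
    margin_px: int = 20
    textured_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("need at least one leaf")
        if not (0.0 <= self.green_fraction <= 1.0):
            raise ValueError("green_fraction must lie in [0, 1]")
        if self.stroke_width_px < 1 or self.leaf_length_px < 2:
            raise ValueError("stroke width/length too small to render")


@dataclass
class LeafTruth:
    rel_height: float       # intended, percent of constructed plant height
    angle_deg: float        # intended inclination after noise + folding
    midpoint: tuple[float, float]   # (col, row) actually drawn
    p1: tuple[int, int]
    p2: tuple[int, int]
    green: bool


@dataclass
class SyntheticTruth:
    """Ground truth of one rendered plant.

    ``foreground`` / ``labels`` are the painted rasters; geometric truths
    (``true_rhc``, ``true_ph_px``) are recomputed from the raster by direct
    pixel summation, so they are what an ideal pipeline should measure.
    """

    leaves: list[LeafTruth]
    foreground: np.ndarray          # bool raster, True = plant
    labels: np.ndarray              # LABEL_* per pixel
    top_row: int                    # raster extent (no droop filtering)
    bottom_row: int
    true_ph_px: int
    true_rhc: float
    true_ala_deg: float
    a_true: float
    b_true: float
    warnings: list[str] = field(default_factory=list)


def _fold_angle(theta_deg: float) -> float:
    """Fold an inclination into [0, 90] (reflect at both boundaries)."""
    t = math.fmod(abs(theta_deg), 180.0)
    return 180.0 - t if t > 90.0 else t


def _stroke(canvas_shape, p1, p2, width_px):
    """Boolean raster of a straight stroke of the given width."""
    out = np.zeros(canvas_shape, dtype=bool)
    rr, cc = draw_line(p1[1], p1[0], p2[1], p2[0])
    out[rr, cc] = True
    radius = (width_px - 1) // 2
    if radius > 0:
        out = dilation(out, disk(radius))
    return out


def generate_plant(spec: SyntheticPlantSpec) -> tuple[np.ndarray, SyntheticTruth]:
    """Render one synthetic plant and its ground truth.

    Returns ``(image, truth)`` where ``image`` is an H x W x 3 uint8 RGB
    raster.  Identical spec (including seed) gives bit-identical output.
    """
    H, W = spec.canvas
    rng = np.random.default_rng(spec.seed)
    bottom_row = H - 1 - spec.margin_px
    top_row = bottom_row - spec.plant_height_px
    center_col = W // 2
    if top_row < 0:
        raise CanvasFitError(
            f"plant height {spec.plant_height_px} + margin does not fit "
            f"canvas height {H}"
        )
    if center_col - spec.leaf_length_px < 0 or center_col + spec.leaf_length_px >= W:
        raise CanvasFitError(
            f"leaf length {spec.leaf_length_px} does not fit canvas width {W}"
        )

    ph = float(spec.plant_height_px)
    # stratified placement over [5, 100]: leaves emerge at roughly regular
    # internodes along the culm, jittered within their stratum
    edges = np.linspace(5.0, 100.0, spec.n_leaves + 1)
    rel_heights = rng.uniform(edges[:-1], edges[1:])[::-1]
    noise = (
        rng.normal(0.0, spec.angle_noise_sd_deg, size=spec.n_leaves)
        if spec.angle_noise_sd_deg > 0
        else np.zeros(spec.n_leaves)
    )
    green = np.ones(spec.n_leaves, dtype=bool)
    n_yellow = round((1.0 - spec.green_fraction) * spec.n_leaves)
    if n_yellow:
        green[rng.choice(spec.n_leaves, size=n_yellow, replace=False)] = False

    leaves: list[LeafTruth] = []
    strokes: list[tuple[np.ndarray, bool]] = []
    for i in range(spec.n_leaves):
        rh = float(rel_heights[i])
        theta = _fold_angle(
            spec.a_true * math.log(rh + 1.0) + spec.b_true + float(noise[i])
        )
        mid_row = bottom_row - rh / 100.0 * ph
        rad = math.radians(theta)
        sin_t, cos_t = math.sin(rad), math.cos(rad)
        # symmetric truncation: both endpoints stay inside [top_row, bottom_row]
        half = spec.leaf_length_px / 2.0
        if sin_t > 1e-9:
            half = min(half, (mid_row - top_row) / sin_t,
                       (bottom_row - mid_row) / sin_t)
        half = max(half, 1.0)
        side = 1 if i % 2 == 0 else -1  # alternate right/left
        # base of the blade sits on the stem; the blade extends outward and
        # upward so its midpoint lands at the intended relative height
        mid_col = center_col + side * half * cos_t
        dc, dr = side * half * cos_t, half * sin_t
        p1 = (int(round(mid_col - dc)), int(round(mid_row + dr)))
        p2 = (int(round(mid_col + dc)), int(round(mid_row - dr)))
        if p1 == p2:
            p2 = (p2[0], p2[1] - 1)  # degenerate short leaf: 2-px vertical
        mid = ((p1[0] + p2[0]) / 2.0, (p1[1] + p2[1]) / 2.0)
        leaves.append(
            LeafTruth(rel_height=rh, angle_deg=theta, midpoint=mid,
                      p1=p1, p2=p2, green=bool(green[i]))
        )
        strokes.append((_stroke((H, W), p1, p2, spec.stroke_width_px), bool(green[i])))

    labels = np.zeros((H, W), dtype=np.uint8)
    # paint yellow leaves first so green organs overwrite at crossings
    for raster, is_green in strokes:
        if not is_green:
            labels[raster] = LABEL_YELLOW
    for raster, is_green in strokes:
        if is_green:
            labels[raster] = LABEL_GREEN
    if spec.stem:
        stem = _stroke((H, W), (center_col, bottom_row), (center_col, top_row),
                       spec.stroke_width_px)
        labels[stem] = LABEL_GREEN

    foreground = labels != LABEL_BG

    image = np.empty((H, W, 3), dtype=np.uint8)
    image[:] = BACKGROUND_RGB
    image[labels == LABEL_GREEN] = GREEN_RGB
    image[labels == LABEL_YELLOW] = YELLOW_RGB
    if spec.textured_background:
        bg_rng = np.random.default_rng(spec.seed + 1)
        for _ in range(12):  # small green speckles for the mask cleaner
            r = int(bg_rng.integers(0, H))
            c = int(bg_rng.integers(0, W))
            rr, cc = draw_disk((r, c), 2, shape=(H, W))
            keep = labels[rr, cc] == LABEL_BG
            image[rr[keep], cc[keep]] = GREEN_RGB

    rows = np.nonzero(foreground)[0]
    t, b = int(rows.min()), int(rows.max())
    truth = SyntheticTruth(
        leaves=leaves,
        foreground=foreground,
        labels=labels,
        top_row=t,
        bottom_row=b,
        true_ph_px=b - t,
        true_rhc=float((b - rows.mean()) / (b - t)),
        true_ala_deg=float(np.mean([lf.angle_deg for lf in leaves])),
        a_true=spec.a_true,
        b_true=spec.b_true,
    )
    return image, truth


def generate_angle_samples(
    a_true: float,
    b_true: float,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    rh_range: tuple[float, float] = (0.0, 100.0),
):
    """Image-free (rel_height, angle) samples from the logarithmic model.

    Relative heights lie on a uniform grid over ``rh_range``; angles are the
    model values plus seeded Gaussian noise, clipped to [0, 90].  Useful for
    testing the model fit without rendering.
    """
    from .anglemodel import AngleSample

    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    rh = np.linspace(rh_range[0], rh_range[1], n)
    angles = a_true * np.log(rh + 1.0) + b_true
    if noise_sd > 0:
        angles = angles + rng.normal(0.0, noise_sd, size=n)
    angles = np.clip(angles, 0.0, 90.0)
    return [AngleSample(float(h), float(a)) for h, a in zip(rh, angles)]


def mask_from_truth(truth: SyntheticTruth) -> PlantMask:
    """The generator's own foreground raster as a PlantMask."""
    return PlantMask(truth.foreground.copy())
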