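"""Batch pipeline: images in, per-plant trait table out.

Runs the full chain on each image — HSV segmentation, mask cleaning,
silhouette geometry (plant height, centroid, RHC), leaf line detection,
vertical angle-model fit, and the GPAR/PAR descriptors — and collects one
trait row per image.  All parameters live in a validated
:class:`PipelineConfig`; unknown keys are rejected so a typo cannot silently
fall back to a default.  For fixed images and config the output is
byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field

from . import anglemodel, descriptors, geometry, leaflines, segmentation
from .anglemodel import AngleSample
from .leaflines import HoughParams
from .segmentation import HSVThresholds, PlantMask

logger = logging.getLogger("vertphen")

TRAIT_COLUMNS = [
    "image", "ph_px", "centroid_height_px", "rhc", "area_px", "perimeter_px",
    "ala_deg", "fit_a", "fit_b", "fit_r", "fit_rmse", "fit_n",
    "gpar", "par", "n_segments", "warnings",
]


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hue_lo: float = 40.0
    hue_hi: float = 180.0
    sat_lo: float = 0.15
    val_lo: float = 0.10
    green_hue_lo: float = 60.0
    green_hue_hi: float = 180.0
    min_component_area: int | None = None   # None = 0.05% of image area
    closing_radius: int = 2
    roi: tuple[int, int, int, int] | None = None  # (top, left, bottom, right)


class HoughConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: int = 20
    min_line_length: int | None = None      # None = 0.05 * plant height
    max_line_gap: int = 5
    rho_res: float = 1.0
    theta_res_deg: float = 1.0
    merge_segments: bool = True
    merge_angle_deg: float = 5.0
    merge_dist_px: float = 5.0
    line_source: Literal["skeleton", "edges"] = "skeleton"


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_fit_points: int = 5


class PipelineConfig(BaseModel):
    """Validated configuration of the whole pipeline; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    hough: HoughConfig = Field(default_factory=HoughConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    droop_quantile: float = 0.005
    par_denominator: Literal["mask", "hull"] = "mask"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate(json.loads(text))


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as an H x W x 3 uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_mask(mask: PlantMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (0 background / 255 plant)."""
    Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L").save(path)


def load_mask(path: str | Path) -> PlantMask:
    with Image.open(path) as im:
        return PlantMask(np.asarray(im.convert("L")) > 127)


def process_image(
    image: np.ndarray,
    config: PipelineConfig,
    name: str = "",
    mask: PlantMask | None = None,
) -> dict:
    """Run the full trait chain on one image; returns one trait row (dict).

    A pre-computed ``mask`` skips segmentation.  Stages that cannot run
    (too few line segments for a fit, say) leave NaNs and a note in the
    ``warnings`` field instead of failing the row.
    """
    seg = config.segmentation
    notes: list[str] = []
    if seg.roi is not None:
        t, l, b, r = seg.roi
        image = image[t:b, l:r]
    if mask is None:
        raw = segmentation.segment_plant(
            image, HSVThresholds(seg.hue_lo, seg.hue_hi, seg.sat_lo, seg.val_lo)
        )
        mask = segmentation.clean_mask(raw, seg.min_component_area, seg.closing_radius)
    if mask.empty:
        raise segmentation.SegmentationError("no plant pixels after segmentation")

    geom = geometry.analyze_mask(mask, config.droop_quantile)
    green = segmentation.green_fraction_mask(
        image, mask,
        HSVThresholds(seg.green_hue_lo, seg.green_hue_hi, seg.sat_lo, seg.val_lo),
    )
    desc = descriptors.compute_descriptors(green, mask, geom, config.par_denominator)

    hough = HoughParams(
        threshold=config.hough.threshold,
        min_line_length=config.hough.min_line_length,
        max_line_gap=config.hough.max_line_gap,
        rho_res=config.hough.rho_res,
        theta_res_deg=config.hough.theta_res_deg,
        merge_segments=config.hough.merge_segments,
        merge_angle_deg=config.hough.merge_angle_deg,
        merge_dist_px=config.hough.merge_dist_px,
    )
    if config.hough.line_source == "skeleton":
        source = leaflines.skeletonize_plant(mask)
    else:
        source = leaflines.detect_edges(mask)
    segments = leaflines.detect_leaf_lines(source, hough, geom, seed=config.seed)

    row = {
        "image": name,
        "ph_px": geom.plant_height_px,
        "centroid_height_px": geom.centroid_height_px,
        "rhc": geom.rhc,
        "area_px": geom.area_px,
        "perimeter_px": geom.perimeter_px,
        "gpar": desc.gpar,
        "par": desc.par,
        "n_segments": len(segments),
        "ala_deg": np.nan,
        "fit_a": np.nan,
        "fit_b": np.nan,
        "fit_r": np.nan,
        "fit_rmse": np.nan,
        "fit_n": 0,
    }
    samples = [AngleSample(s.rel_height, s.angle_deg) for s in segments]
    if samples:
        row["ala_deg"] = anglemodel.average_leaf_angle(samples)
    try:
        fit = anglemodel.fit_angle_model(samples, config.fit.min_fit_points)
        row.update(fit_a=fit.a, fit_b=fit.b, fit_r=fit.r,
                   fit_rmse=fit.rmse_deg, fit_n=fit.n_segments)
        notes.extend(fit.flags)
    except anglemodel.AngleModelError as exc:
        notes.append(f"angle model not fitted: {exc}")
    row["warnings"] = "; ".join(notes)
    row["_segments"] = segments
    row["_geometry"] = geom
    row["_mask"] = mask
    return row


def segments_table(segments: Sequence[leaflines.LeafSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "p1x": s.p1[0], "p1y": s.p1[1], "p2x": s.p2[0], "p2y": s.p2[1],
                "length_px": s.length_px, "angle_deg": s.angle_deg,
                "rel_height": s.rel_height,
            }
            for s in segments
        ],
        columns=["p1x", "p1y", "p2x", "p2y", "length_px", "angle_deg", "rel_height"],
    )


def run_pipeline(
    image_paths: Sequence[str | Path],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    write_artifacts: bool = False,
) -> pd.DataFrame:
    """Process a batch of images into a trait table (one row per image).

    Unreadable or unsegmentable images are skipped with a logged reason; the
    surviving rows are returned (and written to ``out_dir/traits.csv`` when
    an output directory is given).  ``write_artifacts`` additionally writes
    the per-image mask PNG and segment CSV.
    """
    if not image_paths:
        raise ValueError("no input images")
    config = config or PipelineConfig()
    logger.info("pipeline config: %s", config.model_dump())
    rows = []
    failures = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for path in image_paths:
        path = Path(path)
        try:
            image = load_image(path)
            row = process_image(image, config, name=path.name)
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            logger.warning("skipping %s: %s", path, exc)
            failures.append((str(path), str(exc)))
            continue
        segments = row.pop("_segments")
        geom = row.pop("_geometry")
        mask = row.pop("_mask")
        if out is not None and write_artifacts:
            stem = path.stem
            save_mask(mask, out / f"{stem}_mask.png")
            segments_table(segments).to_csv(out / f"{stem}_segments.csv", index=False)
            (out / f"{stem}_geometry.json").write_text(json.dumps({
                "hull": np.asarray(geom.hull).tolist(),
                "centroid": list(geom.centroid),
                "top_row": geom.top_row,
                "bottom_row": geom.bottom_row,
            }))
        rows.append(row)
    table = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    table.attrs["failures"] = failures
    if out is not None:
        table.to_csv(out / "traits.csv", index=False)
    return table
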