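"""Vertical leaf-angle distribution model A_l = a * ln(RH_l + 1) + b.

Leaf inclination in a rice plant varies systematically with height: lower
leaves droop toward the horizontal while upper leaves stand erect, and the
trend is well captured by a logarithmic curve of the relative leaf height.
``a`` (degrees per ln-unit) sets the rise — the vertical heterogeneity of
the canopy — and ``b`` (degrees) is the basal angle at RH_l = 0.  Typical
fits for most growth stages land in a ∈ [0, 20], b ∈ [-20, 90]; a negative
``a`` appears late in heading, when the canopy compacts and upper leaves no
longer stand more upright than lower ones.

RH_l enters the logarithm on the percent scale (0-100), so the printed
parameter ranges above are meaningful; using fractions would rescale ``a``
and shift ``b``.

The model is linear in (a, b) after x = ln(RH_l + 1), so the fit is the
exact ordinary-least-squares solution on the transformed regressor — the
same minimum a generic nonlinear least-squares solver converges to, reached
deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class AngleModelError(ValueError):
    pass


@dataclass(frozen=True)
class AngleSample:
    """One (relative height %, leaf inclination degrees) observation."""

    rel_height: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rel_height <= 100.0):
            raise AngleModelError(
                f"rel_height must lie in [0, 100], got {self.rel_height}"
            )
        if not (0.0 <= self.angle_deg <= 90.0):
            raise AngleModelError(
                f"angle_deg must lie in [0, 90], got {self.angle_deg}"
            )


@dataclass
class AngleModelFit:
    """Fitted (a, b) with goodness-of-fit diagnostics.

    ``r`` is the Pearson correlation between fitted and observed angles;
    ``rmse_deg`` the root-mean-square residual in degrees.
    """

    a: float
    b: float
    n_segments: int
    r: float
    rmse_deg: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def _design(rel_heights: np.ndarray) -> np.ndarray:
    return np.log(rel_heights + 1.0)


def fit_angle_model(
    samples: Sequence[AngleSample], min_fit_points: int = 5
) -> AngleModelFit:
    """Least-squares fit of the logarithmic leaf-angle distribution.

    Minimises sum((angle - a*ln(rel_height+1) - b)^2) exactly via OLS on the
    transformed regressor.  Refuses (raises) with fewer than
    ``min_fit_points`` samples or with no variance in the heights, where the
    slope is unidentifiable.
    """
    n = len(samples)
    if n < min_fit_points:
        raise AngleModelError(
            f"need at least {min_fit_points} (angle, height) pairs, got {n}"
        )
    rh = np.array([s.rel_height for s in samples], dtype=float)
    y = np.array([s.angle_deg for s in samples], dtype=float)
    x = _design(rh)
    if np.ptp(x) < 1e-12:
        raise AngleModelError(
            "all relative heights identical: slope a is unidentifiable"
        )
    X = np.column_stack([x, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = a * x + b
    resid = y - fitted
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.std(fitted) < 1e-12 or np.std(y) < 1e-12:
        r = 1.0 if rmse < 1e-12 else 0.0  # flat data/fit: correlation undefined
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    fit = AngleModelFit(a=float(a), b=float(b), n_segments=n, r=r, rmse_deg=rmse)
    fit.flags = validate_fit_range(fit)
    return fit


def predict_angle(fit: AngleModelFit, rel_height: float) -> float:
    """Model angle at a relative height: a * ln(rel_height + 1) + b.

    Unclamped — the prediction may leave [0, 90] for extreme parameters;
    the caller decides whether to clip.
    """
    if not (0.0 <= rel_height <= 100.0):
        raise AngleModelError(
            f"rel_height must lie in [0, 100], got {rel_height}"
        )
    return fit.a * math.log(rel_height + 1.0) + fit.b


def average_leaf_angle(samples: Iterable[AngleSample]) -> float:
    """ALA: unweighted arithmetic mean inclination over all leaf segments."""
    angles = [s.angle_deg for s in samples]
    if not angles:
        raise AngleModelError("ALA undefined for an empty sample list")
    return float(np.mean(angles))


#: Parameter ranges observed at most growth stages; excursions are flagged,
#: not rejected (negative a is biologically meaningful late in heading).
TYPICAL_A_RANGE = (0.0, 20.0)
TYPICAL_B_RANGE = (-20.0, 90.0)


def validate_fit_range(fit: AngleModelFit) -> list[str]:
    """Warn (never error) when (a, b) leave their typical ranges."""
    flags = []
    if fit.a < TYPICAL_A_RANGE[0]:
        flags.append("a below typical range (late-heading canopy compaction?)")
    elif fit.a > TYPICAL_A_RANGE[1]:
        flags.append("a above typical range")
    if fit.b < TYPICAL_B_RANGE[0]:
        flags.append("b below typical range")
    elif fit.b > TYPICAL_B_RANGE[1]:
        flags.append("b above typical range")
    return flags
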