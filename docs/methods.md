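# Methods

This note describes what `vertphen` computes, the assumptions behind each
stage, the parameters that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Scope and model of the scene

The toolkit assumes a single potted plant photographed from the front
against a background that is separable in HSV space. All traits are either
dimensionless (RHC, GPAR, fit correlation), angular (leaf inclinations), or
in raw pixels (plant height, area, perimeter, PAR); no metric calibration is
attempted, because the two core descriptors are deliberately scale-free.

## Segmentation

Pixels are classified by an axis-aligned box in HSV: hue bounds in degrees
(0–360), minimum saturation and value as fractions. Two boxes are used:

* **plant box** (default hue 40–180°, s ≥ 0.15, v ≥ 0.10): live *and*
  senescent foliage versus background. The band reaches below green so that
  yellowing organs (hue ≈ 55°) stay inside the plant mask; otherwise the
  greenness ratio would be 1 by construction.
* **green box** (default hue 60–180°): green organs only, for GPAR. It is a
  strict subset of the plant box, so the green mask is always a subset of
  the plant mask.

Neither box wraps around hue 0 — green never straddles the red origin —
and wraparound is deliberately unsupported. Cleaning removes connected
components smaller than 0.05 % of the image area and applies a morphological
closing of radius 2 px: enough to suppress background clutter without
eroding 2–3-px leaf strokes. Region-of-interest cropping is an explicit
config rectangle, not automatic detection, since pot shots are framed
manually. **On noise-free synthetic renders the closing is disabled**
(`closing_radius: 0`): there is no clutter to remove, and closing welds
crossing strokes into blobs that distort the skeleton downstream. The
defaults stay as stated for photographs.

## Silhouette geometry and RHC

Heights are measured upward from the plant's bottom row in pixels; the
raster's top-origin convention is inverted exactly once, in the geometry
module.

* **Extent / plant height.** Drooping leaf tips should not stretch the
  measured plant height, but no published filtering rule exists; the choice
  here is quantile-robust: `top_row` and `bottom_row` are the `q` and
  `1 − q` order statistics of the foreground row distribution
  (`droop_quantile`, default q = 0.005 at each end, 0 disables). The filter
  is symmetric because it is unclear whether only the bottom should be
  filtered; symmetric filtering is self-consistent and reproducible.
* **Centroid** is the unweighted mean of foreground pixel coordinates (the
  first-order moments of the binary mask) — the silhouette, not intensity,
  carries the signal.
* **RHC** = (bottom_row − centroid_row) / (bottom_row − top_row). Pixels
  outside the filtered extent are excluded from the moment sum so that
  0 < RHC < 1 always holds for masks spanning ≥ 2 rows. RHC is invariant
  under horizontal translation and mirroring, and under uniform rescaling up
  to a discretisation error ≤ 2/PH.
* **Contour and perimeter.** The outer boundary of the largest component is
  traced with Moore-neighbour tracing (Jacob's stopping criterion), and arc
  length uses the 8-connected metric: 1 per axis step, √2 per diagonal. A
  one-pixel mask has perimeter 1 by convention. These conventions matter
  because PAR depends on them; they are fixed and documented rather than
  optimal.

## Leaf lines

The probabilistic Hough transform runs on the medial-axis skeleton of the
mask by default (1-px input, cleaner than edges; Canny edges are available
as an option but measured noticeably worse on crossing strokes). Defaults:
ρ = 1 px, θ = 1°, accumulator threshold 20, `min_line_length` = 0.05 × PH
(tying sensitivity to plant size, not image size), `max_line_gap` = 5 px.
The Hough sampling is seeded; fixed seed ⇒ fixed output.

Post-processing, in order:

1. **Merging.** The probabilistic transform fragments one leaf into several
   near-collinear segments. Fragments are greedily clustered: a segment
   joins the longest compatible representative when inclinations differ by
   ≤ 5°, its midpoint lies within 3 px of the representative's carrier
   line, *and* its projection onto that line overlaps the cluster span or
   falls within 10 px of it. The gap condition keeps distinct collinear
   leaves separate; the 3-px distance (rather than a laxer 5 px) avoids
   merging adjacent leaves whose carrier lines run ~5 px apart at steep
   inclinations. Each cluster is replaced by its longest-span
   representative. Merging can be disabled.
2. **Scene furniture.** Near-horizontal segments longer than half the image
   width are pot rim or ground. Near-vertical segments (> 88°) are culm
   rather than leaf when they span > 0.4 × PH **or** their midpoint sits on
   the silhouette's centroid column (the culm axis) — the second clause
   catches short culm fragments left after the main culm line is removed.
   Both filters run after merging so fragments are judged by their full
   span, and both can be switched off.

Each surviving segment gets an unsigned inclination
`atan(|Δrow|/|Δcol|) ∈ [0°, 90°]` — left- and right-leaning leaves are
equivalent — and a relative height from its midpoint, clipped to [0, 100].
An optional junction-pruning step (cutting skeleton branch points before the
transform) exists but is off by default: on the synthetic benchmark it did
not improve parameter recovery.

## The angle-distribution model

`A = a·ln(RH + 1) + b` with RH on the **percent** scale (0–100). Using
fractions would rescale `a` and shift `b` and make the typical ranges
(`a ∈ [0, 20]`, `b ∈ [−20, 90]`) meaningless. The model is linear in
(a, b) after `x = ln(RH + 1)`, so the fit is the closed-form least-squares
solution on the transformed regressor — deterministic, and identical to the
minimum a generic nonlinear solver would reach. At least 5 samples with
non-degenerate height variance are required (two parameters plus meaningful
residual degrees of freedom). The fit is unweighted; an optional
length-weighted variant was considered and rejected as the default because
pairs should count equally. Fits outside the typical ranges are flagged,
never rejected: a negative `a` is biologically meaningful late in heading,
when the canopy compacts. ALA is the unweighted mean inclination over
detected segments (segment-mean, since leaf identity is not tracked).

## Synthetic plants

The generator emulates what the pipeline models: a plant whose leaves are
straight elongated strokes.

* Canvas 480 × 420, plant height 300 px, 30 leaves, stroke width 3 px, leaf
  length 90 px, vertical stem, uniform mid-gray background (zero
  saturation — outside every HSV box, so segmentation is pixel-exact by
  construction). Pure green (0,255,0) and senescent yellow (255,234,0 —
  hue ≈ 55°) paint the organs; a `green_fraction` parameter controls their
  mix and hence the true GPAR.
* Leaves are placed at stratified-jittered relative heights over [5, 100]
  (one per stratum): rice leaves emerge at roughly regular internodes, and
  iid-uniform placement produces overlapping collinear strokes that no line
  detector could separate. Leaves alternate sides, base on the stem, blade
  extending outward and upward so the **midpoint** lands at the intended
  relative height; blades are truncated symmetrically about their midpoint
  so they never leave the stem's vertical extent.
* Each leaf's inclination is `a·ln(RH+1) + b` plus Gaussian noise (default
  σ = 3°), folded into [0, 90]. The recorded truth pair (RH, angle) is the
  *intended* pre-rasterisation value — at σ = 0 it satisfies the model
  equation exactly; the drawn integer endpoints (also recorded) differ by
  sub-degree rasterisation error. Geometric truths (RHC, PH) are recomputed
  from the emitted raster by direct pixel summation.
* Rendering uses integer raster operations only: identical spec + seed is
  bit-identical across platforms. Strokes are straight by design — a
  `curvature` stress option is deliberately absent from the truth
  guarantees. The generator does not emulate: leaf curvature, width
  taper, specular highlights, soil/pot texture (beyond an optional speckle
  mode that exercises mask cleaning), or overlapping tillers. Passing tests
  therefore demonstrate correctness of the *measurement chain*, not
  robustness to photographic nuisance.

## Statistics

One-way ANOVA with Tukey HSD post-hoc comparison at 95 % confidence, with
the usual star convention (\* p < 0.05, \*\* p < 0.01, \*\*\* p < 0.001).
Zero within-group variance (which synthetic fixtures hit) is reported by the
limiting convention — p → 0 if any means differ, p = 1 if all observations
are equal — with a degenerate flag. MLR is ordinary least squares;
collinear or constant columns are dropped via rank checks with a warning
naming them; the score is the Pearson correlation between fitted and
measured response. Measured responses (dry matter, extinction coefficient)
are consumed from the trait table and never derived from images. Rows are
per-sample by default; aggregation to pot means is the caller's choice.

## Verification strategy and problem sizes

Every numeric claim is checked against an independent oracle at desk scale:
brute-force pixel sums for centroid/RHC/extent (50 random blobs), a
boundary-pixel scan for contours, an O(n·h) containment check for hulls,
closed-form normal equations for both regressions, explicit sums of squares
for ANOVA, and the generator's ground truth for the image chain. Single
strokes at every integer angle 0–90° are recovered within 2° (measured
≈ 1°). Stroke-level recovery (≥ 80 % of leaves with ≤ 3° / ≤ 3-point
errors) is asserted on 12-leaf plants, where strokes are individually
resolvable; at the default 30 leaves neighbouring strokes overlap and
per-stroke identification becomes ill-posed for any detector, so the dense
case is covered by parameter recovery instead.

Parameter recovery is verified two ways. Image-free: 100 seeded replicates
at n = 200 samples, σ = 3°, with tolerances set at three standard errors
from OLS theory (≈ 0.65° /ln-unit for `a`, ≈ 2.5° for `b` at these
conditions — computed in the test, not assumed). End-to-end: for
(a, b) ∈ {(5, 20), (10, 30), (15, 10)}, the mean fit over five replicate
renders must land within |Δa| ≤ 2, |Δb| ≤ 5. The averaging mirrors
multi-plant experimental designs and is necessary in principle: with ~28
segments per render and σ = 3° of angle noise, a *perfect* detector already
has a per-render SD of b̂ ≈ 2.7°, so a per-render bound of 5° would mostly
measure generator noise. Problem sizes throughout (50 blobs, 91 strokes,
100 replicates, 5 renders) were chosen as the smallest that make the checks
statistically meaningful.

## Known limitations

* One plant per scene; no occlusion or multi-tiller separation.
* Hue thresholds are fixed boxes, not learned; no wraparound.
* Leaf identity is not tracked across images or dates.
* The angle model is the logarithmic family only; Weibull or bell-shaped
  alternatives used for other canopies are out of scope.
* PAR values depend on the documented perimeter metric; compare only within
  runs of this package.
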