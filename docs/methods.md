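# Methods

## Centerline model and curvature estimation

A vessel segment is represented by its centerline, an ordered point
sequence C(t) = (x(t), y(t)) indexed by the integer parameter
t = 1…N in pixel units.  The curve must be *regular* (C′(t) ≠ 0): steps
between consecutive points are at most √2 (8-neighbor pixels or
smoothed/analytic interpolants), no two consecutive points coincide,
and N ≥ 21 so that the full one-sided derivative stencil fits at the
segment ends.

First and second coordinate derivatives at point m are estimated by
weighted least squares on the second-order Taylor expansion

    f(m+p) = f(m) + f′(m)·p + ½ f″(m)·p² + ε,

one equation per offset p ∈ {±4, ±8, ±12, ±16, ±20} with m + p in
range, weights 1/|p| (distant neighbors count less).  Interior points
use 10 equations; at the extreme points the usable set shrinks to the 5
one-sided offsets, which N ≥ 21 keeps well-posed.  Each per-point system
has two unknowns (the offsets from the known central value), so the
solution is a closed-form 2×2 solve shared by all points with the same
stencil.  The four derivative sequences are then smoothed by a centered
3-term moving average whose window truncates symmetrically at the ends
(no data is invented beyond the endpoints).  Signed curvature follows as

    κ = (y″x′ − y′x″) / (x′² + y′²)^{3/2},

with a hard error (not a clamp) if the squared speed falls below 1e−6,
since that violates regularity.

The geometric parameters are the chord length D (endpoint distance) and
the line integrals L = ∫ ds, TK = ∫ |κ| ds, TSK = ∫ κ² ds, evaluated by
the composite trapezoidal rule on the unit parameter grid with
ds = √(x′² + y′²) dt.  The trapezoidal rule matches the pixel-index
parametrization and is O(h²) accurate; no sub-pixel re-parametrization
is attempted.  **TK integrates |κ|, not signed κ**: the total-curvature
indices are absolute-curvature measures, and signed integration would
cancel on S-shaped vessels, collapsing their measured tortuosity.  The
eight indices follow algebraically; T1 is computed as DF − 1 on the
same arithmetic path, so DF/T1 results are duplicated to the last bit.

### Accuracy of the estimator

Two error sources matter and are quantified by the tests:

* **Taylor truncation.**  With offsets up to ±20 the quadratic model is
  exact for polynomial coordinates (the linear/quadratic tests assert
  ≤ 1e−9) but biased on curved arcs when the stencil span is large
  relative to the radius of curvature: on unit-arc-step circles the
  curvature bias is ≈ 6% at R = 30, 2% at R = 50 and 0.9% at R = 80.
  Analytic curves are therefore sampled finely (0.1 px arc steps by
  default), which shrinks the span in parameter units and recovers
  closed-form arc geometry to ≤ 0.1%.
* **Rounding noise.**  Integer-pixel curves carry ±0.5 px noise; after
  coordinate smoothing the per-point curvature still fluctuates with a
  standard deviation of order 1e−3 px⁻¹.  Pointwise curvature on
  skeleton-like curves is accordingly noisy, while aggregates are not:
  the mean interior |κ| of a digital R = 80 circle recovers 1/R within
  2%, and the integrals D, L (±2%) and TK (±5%) are stable end to end.

## Landmarks and M/D alignment

The optic disc is located as the brightest region of each frame, the
macula as the darkest, on a copy median-filtered per RGB channel with a
21×21 window (about three times the thickest vessel diameter) and
replicate border padding, so border effects never bias the darkest-point
search.  Per channel, all pixels attaining the extremum are reduced to
their coordinate midpoint, and the three channel midpoints are averaged
with equal weight; fractional coordinates are kept.  For landmark search
only, intensities are quantized to 8 bits first, which makes the integer
rank-median exact and fast; measurements never touch the smoothed copy.
The disc radius is estimated as one fifth of the disc–macula distance,
taken from the D frame by default.

Alignment translates the M frame by the *integer-rounded* disc-center
displacement.  Interpolation is deliberately forbidden: resampling would
alter pixel values and hence the extracted geometry, so the sub-pixel
residual (< 0.5 px, recorded in the `RoiPair`) is accepted instead.  The
common ROI is the intersection of the two fields of view (black corners
excluded by thresholding near-zero luminance and keeping the largest
connected region) minus the estimated disc disk; every retained pixel is
a verbatim copy of its source.

## Vessel extraction

A per-vessel ROI pads the hand line's bounding box by 20 px.  The
default binarizer targets dark vessels on a slowly varying background:
it subtracts a 31-px median estimate of the background from the green
channel and thresholds the response with Otsu's method.  The binarizer
is pluggable — any callable producing a foreground mask can replace it,
since the downstream chain does not depend on its internals.  A
morphological closing with a 7-px-radius discrete disk (the thickest
vessel width) smooths irregularities and bridges small gaps; the
connected component reaching both tentative-endpoint neighborhoods
(10 px disks) is then kept.  Closing precedes component selection so
that a mask gap across the vessel does not abort the segmentation.

The mask is thinned to a 1-px, 8-connected skeleton (topology-preserving
thinning; the tests constrain properties, not a specific algorithm's
bit pattern).  Skeleton pixels are classified by 8-neighbor count
(1 → endpoint, ≥ 3 → branching); candidates for the two *principal*
endpoints are the endpoint and branching pixels plus skeleton pixels on
the ROI border (where a vessel may leave the crop), and the candidate
nearest each tentative endpoint wins, with distance ties broken
lexicographically by (row, col) for determinism.  Needle branches are
pruned by repeatedly deleting every non-principal endpoint pixel and
relabeling; each pass erodes every spur by one pixel, so the procedure
terminates in at most as many passes as there are skeleton pixels and
never touches the principals.  A spur's base pixel can survive when it
retains ≥ 2 path neighbors (it is then never endpoint-labeled); it is
harmless because the final parametrization follows the shortest skeleton
path between the principals, which is identical to naive neighbor
walking on simple paths but robust when branching pixels survive on the
path.  The pixel string starts at the principal closest to the image
origin, and a final 3-term moving average completes the parametrization.

## Concordance statistics

Per index, agreement across the frame-center change is summarized by the
Bland–Altman bias (mean of the D − M differences), the sample standard
deviation (n − 1 — standard agreement-analysis practice), the limits of
agreement bias ± 1.96·sd (multiplier configurable), the count of points
outside the limits (≈ 5% under normality), and the two-sided paired
t-test of zero mean difference.  Heterogeneity between eyes is checked
with a one-way fixed-effects ANOVA of the differences grouped by eye.
No multiple-testing correction is applied across the eight indices; raw
p-values are reported.  Index consistency uses pairwise Spearman rank
correlations (average ranks on ties) and Pearson correlations, computed
on the pooled M + D values by default (configurable to either frame),
and an agglomerative dendrogram on the 1 − r dissimilarity with
complete linkage by default (single and average available; the DF/T1
zero-height merge and the curvature-vs-length cluster split hold under
all three).

## Synthetic data

The generator family stands in for clinical acquisition and defines the
conditions the tests run under:

* **Analytic curves** (line, circular arc, sinusoid, random sum-of-sines
  composite) carry ground truth: closed form for lines and arcs,
  adaptive quadrature refined to ~1e−10 relative error for sinusoids and
  composites — an oracle independent of the estimators under test.
  Default sampling is 0.1 px arc steps.
* **Rasterized vessels** are dark tubes (dilation of the pixelated
  centerline by a disk, giving round end caps) on a lighter background
  with seeded Gaussian noise; the true centerline pixels and end pixels
  are returned as ground truth and tentative endpoints.
* **Fundus phantoms** build one scene — reddish background with a mild
  illumination gradient, a bright Gaussian disc blob (the unique
  brightest region in every channel), a dark macula blob (the unique
  darkest), and circular-arc vessels confined to the region both
  croppings share, each with exact closed-form truth — and crop it twice,
  centered on the macula and on the disc.  The disc–macula distance is
  one third of the frame width, mimicking typical fundus geometry, and
  the frame-center change is pure re-cropping (integer translation, no
  resampling).  A small per-frame noise field (sd 1.5) emulates
  re-imaging so paired measurements differ; an optional mild radial
  distortion per frame is available but off by default.
* **Paired difference tables** draw per-vessel M values from a uniform
  magnitude range and add a configurable bias plus Gaussian noise whose
  sd grows linearly with magnitude — the funnel shape of the clinical
  Bland–Altman plots — with rows labeled cyclically across four eyes.

What the phantoms deliberately do **not** model: vessel caliber
variation and branching statistics, pathology (lesions, haemorrhage),
chromatic or optical aberrations, and any physical re-imaging transform
beyond translation plus noise.  Passing tests therefore demonstrate the
correctness and calibration of the measurement chain and statistics on
controlled geometry, not detection robustness on clinical images — in
particular, the phantom study does not reproduce the clinical finding of
a systematic positive D − M bias, because its two framings really do
image the same scene.

## Problem sizes and determinism

Every generator is deterministic under a fixed seed, and the pipeline
echoes its effective configuration with the report.  The shipped
demonstrations use one phantom pair with up to 10 vessels at the native
768×806 frame size (≈ 10 s end to end), 20 seeds for landmark
calibration at 384×402, 100 000 draws for Bland–Altman coverage and
1000 null simulations (n = 40; four groups of 10) for test calibration —
sizes chosen so the full suite runs on a laptop in a few minutes while
keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* The binarizer is a deliberately simple background-flattening
  threshold; heavily non-uniform clinical illumination or low-contrast
  vessels need a stronger segmentation plugged into the same slot.
* Pointwise curvature on integer-pixel curves is noisy (see above); only
  integrated or averaged curvature quantities should be interpreted.
* The Taylor stencil biases curvature on very tight bends
  (radius ≲ 30 px at unit steps); indices of such vessels are
  systematically slightly overestimated.
* Landmark localization assumes the disc is the brightest and the macula
  the darkest structure; bright lesions violate this.
* Vessels are matched across frames by shared identifiers in the
  configuration; there is no automatic cross-frame vessel matching.
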