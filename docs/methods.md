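# Methods

This note records the model, the conventions, and the design choices made
where the problem was genuinely open, in enough detail to re-derive every
number the package computes.

## Coordinates and units

All grids are 0-based `(row, col)`.  Row 0 is the seat-front edge (toward
the knees); rows increase toward the seat rear; the subject's left hip lies
on the smaller-column side (this holds for body rotations within ±45°,
which covers the ±40° working range).  Hip coordinates are reals: manual
marks and rotated template geometry are naturally sub-pixel even though the
correlation argmax lands on integer pixels.  One pixel corresponds to
11.5 mm on the sensor; `px_to_cm` reports centimetres at 3 significant
figures.

## Preprocessing

`preprocess` = L1-normalize(mask ⊙ smooth):

* **Mask**: pixel > 0.45 × mean over *all* pixels (zeros included; contrast
  with the localizer's weakening, whose mean is over the pressure area
  only).  The comparison is strict (`>`); the choice only affects pixels
  exactly at threshold.
* **Morphology**: opening then closing with a 3×3 square element (radius 1,
  the smallest nontrivial element).  Border convention is the standard
  identity-element padding (erosion pads foreground, dilation background),
  so a body region touching the seat-front edge is not eroded.
* **Smoothing**: 3×3 Gaussian, σ = 0.8, kernel renormalized to sum 1,
  reflect (half-sample symmetric) padding so edges are not darkened.
* **Normalization**: divide by the masked-image sum; output sums to 1, so
  every regional sum downstream is a fraction of body weight.

The whole pipeline is algebraically invariant to positive scaling of the
input (threshold and normalization are both relative); in floating point
the identity holds to machine rounding (~1e−15), which is how the tests
assert it.  An image whose mask removes everything raises
`empty image after masking` rather than returning NaNs.

## Template bank

Geometry (pixels): hip disc radius r₁ = 7, strong-site radius r₂ = 3,
hip separation d = 12, penalty thickness c = 4, caudal rearward offset
h = 3, forward rectangle length l = 9.  Values: v_weak = 1 (fixed
reference — global scaling of all values only rescales responses),
v_medium = 2, v_strong = 5, penalty slope k = −0.3.

Construction details that were open choices:

* **Variant tier assignment** (the four variants are published only as a
  figure): variant 1 = strong at both hip cores and the caudal disc;
  variant 2 = strong at the left-hip core only; variant 3 = right-hip core
  only; variant 4 = caudal disc only; non-strong candidate sites take the
  medium tier, the rest of the reward area (hip discs outside the cores,
  thigh rectangles) the weak tier.  Rationale: the three candidate
  high-pressure sites generally do not peak simultaneously.
* **Thigh rectangles** carry the uniform weak tier along their full length
  (no taper), spanning rows [−(r₁+l), 0] and ±r₁ laterally about each hip
  center.
* **Penalty band**: pixels within distance c *outside* the union of the
  three discs, restricted to the rear half-plane (canonical row ≥ 0), value
  k × (distance beyond the disc boundary) ∈ [k·c, 0).  No penalty across
  the forward thigh area.
* **Rasterization**: a pixel belongs to a region iff its center lies in the
  analytic region; boundary ties go to the higher-priority region
  (strong > medium > weak > penalty > neutral).  Rotation re-rasterizes the
  rotated analytic geometry instead of resampling pixels, keeping the
  reward/penalty/neutral sign partition crisp.  The template grid is the
  tight bounding box of all regions plus a 1 px margin; the anchor (the
  rotation center and the correlation reference point) is the hip midpoint.
* **Reward-sum equalization** is enforced across the *entire* bank, not
  only across the four variants at angle 0: re-rasterization at different
  angles changes reward pixel counts by up to ~6% (axis-aligned region
  boundaries at 0° pass exactly through pixel centers), and an unequalized
  bank systematically pulls the winning angle toward the larger-sum
  templates.  Equal correlation weight per template is the stated purpose
  of equalization, so each rotated template's reward pixels are scaled to
  the variant-1/angle-0 reference sum; penalty pixels are never scaled.

Region masks depend only on (geometry, angle) and are cached; a bank for
new tier values is a cheap linear fill of cached masks, which is what makes
the optimizer's 81-point grid search fast.

## Localization

`locate_hips` = weaken → correlate with all 36 templates → global argmax.

* **Weakening** runs on the preprocessed (normalized) image — the order is
  scale-consistent, and since both operations are positively homogeneous
  the argmax is unchanged by input scaling.  `MeanVal` is the mean over
  strictly positive pixels ("the pressure area").
* **"Convolution"** is implemented as cross-correlation (no kernel flip):
  the template is slid over the image and scored where it caters to the
  pressure pattern; a flipped kernel would mirror the asymmetric penalty
  band.
* **Padding** is zero: off the sensor there is no pressure, so a template
  hanging off the seat edge is scored against zeros.
* **Tie-breaking** (argmax ties are real on plateaus): smaller |angle|
  first (the commonest sitting case), then ascending signed angle, then
  lower variant id, then row-major position.  Fully deterministic.

Predicted hip/caudal centers = integer argmax position + the winning
template's rotated (real-valued) offsets, so predictions are sub-pixel.

## Parameter optimization

Objective: J = Σᵢ(dist_lᵢ + dist_rᵢ)/(2N), Euclidean pixel distances,
predicted-left to marked-left and right to right (no Hungarian swap: within
the ±40° range a left/right flip cannot occur).  J is piecewise constant in
the parameters — the argmax moves in jumps — so the search is an exhaustive
grid: defaults v₂ ∈ {1.5, 2, 3}, v₃ ∈ {4, 5, 6}, k ∈ {−0.1, −0.3, −0.5},
WeakenCoef ∈ {2.0, 2.8, 3.6} (81 points, centered on the canonical
optimum), combinations violating 1 ≤ v₂ ≤ v₃ skipped, ties to the earliest
grid-order point.  Images are preprocessed once per search; only template
values and the weakening cap change per point.  By default the whole
annotated set is used (no train/validation split), matching how the
canonical parameters were obtained.

## Features and classification

Features: sums of the normalized image over discs of radius 7/7/3 around
the localized left-hip/right-hip/caudal centers (same center-in-disc rule
as template rasterization; disc parts outside the grid contribute 0; the
discs overlap slightly, so their sum may exceed the mass of the union).
Features are computed from *predicted* centers — the pipeline is evaluated
end to end, not from the manual marks.

Standardization: z-score with the population (divide-by-n) standard
deviation.  Standardizing the whole dataset before cross-validation would
leak test-fold statistics, so by default the standardizer is fit on each
training fold only; `dataset_standardize=True` restores whole-dataset
behavior for comparison.

SVMs: one-vs-rest binary max-margin classifiers (scikit-learn SVC,
tol = 1e−4); prediction is the argmax of the per-class decision values.
Kernel parameterizations: polynomial (β⟨x,x′⟩+θ)^d, Gaussian
exp(−γ‖x−x′‖²), sigmoid tanh(β⟨x,x′⟩+θ); canonical parameter sets are
polynomial C = 1.3, β = 1.4, θ = 0.8, d = 3; Gaussian C = 0.2, γ = 2;
sigmoid C = 0.4, β = 0.2, θ = 0.2.  Cross-validation is stratified by label
(5 folds, seeded shuffling); subject-wise folds are available via
`groups=`.  Kernel grid search is exhaustive with ties to the earliest
point.

## Evaluation statistics

Per image: dist_l, dist_r, and the maximum positioning deviation
max(dist_l, dist_r).  The report aggregates a histogram over unit pixel
intervals, its cumulative curve, and proportions of images with maximum
deviation strictly below 3 px — overall, per subject, and per rotation
bucket |angle| ∈ [0, 15), [15, 30), [30, 45] (boundary inclusion was an
open choice; samples beyond 40° cannot occur with the default ranges but
would fall in the large bucket).

## Synthetic scene generator

The generator emulates the *statistical structure* of real seat-pressure
data, not its physics:

* **Hip blobs**: truncated two-component Gaussians (base σ = r/2.5 plus a
  sharp core σ = r/4.5 at 0.8 relative weight, peak-normalized).  The sharp
  core models the ischial bone's pressure spike — the very feature the
  localizer's weakening step exists to clip.  A single smooth Gaussian
  turned out to be *flatter after weakening than any real image would be*
  (the cap flattened most of the blob, destroying adjacent-angle contrast),
  so the two-component form is a fidelity requirement, not a tuning knob.
* **Caudal blob**: single truncated Gaussian, radius 3.  Its peak amplitude
  depends on which site is high-pressure in that frame: 0.45 (hip-type
  image) vs 1.25 (caudal-type image), relative to hip peak 1.0.  Under the
  default `mixed` mode the caudal-type state is drawn with probability 0.85
  when leaning back and 0.10 otherwise (posterior pelvic tilt loads the
  coccyx); the two high-pressure patterns do not co-occur.
* **Thigh ridge**: forward rectangles with a cosine lateral profile and
  linear decay toward the knees, amplitude 0.25.
* **Posture multipliers** on (left, right, caudal, thigh) masses:
  upright (1, 1, 1, 1); lean left (1.5, 0.6, 0.9, 1); lean right mirrored;
  lean back (0.85, 0.85, 1.7, 0.7).  Leg-crossed variations scale the two
  thigh ridges by (0.45, 1.25) — a crossed leg is lifted off the seat; the
  "free" variation draws one of the three concrete poses plus ±10%
  amplitude jitter.
* **Rigid motion**: rotation uniform in ±40°, translation uniform in ±2 px
  per axis, about the grid center; per-subject weight scale uniform in
  [0.8, 1.2] drawn once per subject.  The annotated structures (hip +
  caudal discs) must fit the grid at any rotation; the thigh ridge may clip
  at the seat-front edge, exactly as real knees extend past the sensor.
* **Noise**: additive clipped Gaussian (σ = 0.02 of the unit hip peak)
  everywhere, plus Poisson(1.5) isolated spike pixels off the body
  (external interference for the preprocessing mask to remove).
* **Behind the body support** (more than r₁ behind the hip line) there is
  no signal before noise — the property motivating the rear penalty band.

All magnitudes are free parameters of the emulation (no quantitative
pressure values are published for the real data); they were fixed from the
qualitative description above and are configuration defaults, not fitted
quantities.

**What passing tests show — and don't.**  On this generator the pipeline
attains ~1 px mean deviation, >99% of images below 3 px, exact rotation
identification in ≥90% of noise-free bank-angle scenes, and ~88–90%
polynomial-kernel CV accuracy (the polynomial ≥ Gaussian ≥ sigmoid ordering
reproduces).  These numbers validate the *algorithmic contracts* —
correlation equals brute force, grid search is exhaustive, features order
as designed — under data whose blobs are ideal Gaussians with exactly the
assumed geometry.  Real images have asymmetric, subject-specific blobs,
correlated sensor noise, and postural diversity the generator does not
model, so real-data accuracy cannot be inferred from these synthetic
results.

## Problem sizes

Defaults were chosen to keep every computation interactive on one CPU: the
full synthetic study is 800 images (seconds to localize end to end thanks
to FFT correlation and mask caching); the optimizer demonstration searches
81 grid points on 50 images; classification demonstrations use 192–800
images.  All sizes are parameters.

## Known limitations

* The discrete 10° angle grid bounds rotation accuracy; no sub-pixel or
  sub-angle refinement of the argmax is attempted.
* Single-person images only; no multi-hypothesis output, no temporal
  smoothing across frames.
* The three-feature classifier cannot distinguish postures that move
  pressure outside the three discs (e.g. forward leaning); that would need
  additional regional features.
* Generator realism is qualitative (see above); it is a test harness and a
  study-design mirror, not a biomechanical simulation.
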