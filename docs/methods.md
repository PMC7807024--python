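# Methods

This note documents the models, parameter choices and known limitations of
the cvquant pipeline, in the order data flows through it.

## Preprocessing

Speckle is suppressed by a median filter (default window 3 px) followed by
Gaussian smoothing (default σ = 1 px), then a white top-hat with a disc
structuring element (default radius 8 px) removes background structures
wider than any vessel of interest while keeping bright curvilinear features
at full contrast. All borders are handled by reflection; a dark frame
around the image would otherwise inflate the top-hat response at the edges.
The defaults are the smallest values that preserve a 3-px synthetic ridge
in the test suite while still reducing background variance; all are exposed
under the `preprocess:` config block.

The vessel enhancer is a phase-symmetry measure built from a log-Gabor
quadrature filter bank: default centre wavelengths 4, 8 and 16 px (covering
capillary to arcade calibres at typical en-face sampling), 6 orientations
over 180°, radial bandwidth σ_f = 0.55. At each pixel the even (line) and
odd (edge) responses are pooled as
`Σ [e − |o|]₊ / (Σ √(e² + o²) + ε)`, with polarity fixed to bright ridges.
The measure lies in [0, 1], peaks on ridge centerlines, and is invariant to
multiplicative intensity rescaling up to the stabiliser ε = 1e−9 (observed
deviation < 1e−4 for a 2× rescaling). A monogenic-signal variant was
considered and not implemented; the oriented bank directly provides the
orientation pooling the segmentation channel needs. Because the phase map
is centerline-peaked rather than body-filling, it enters the segmentation
as a *secondary* channel (see weights below).

## Segmentation

Binarization minimizes a two-phase piecewise-constant (Chan–Vese-type)
region energy over the hybrid channels — denoised intensity (weight 1.5)
and phase response (weight 0.5) — plus a boundary regularizer equal to the
pixel area of the γ-neighbourhood of the zero level set (γ = 2 px, weight
0.05, both scale-free after division by the pixel count). An area-of-
neighbourhood regularizer, unlike contour length, does not penalize the
highly irregular boundaries of fine vascular networks. The channel weights
were tuned once on the synthetic suite: weighting phase heavily collapses
the partition toward skeleton-like output because the phase response is
thin by construction.

The level-set function is initialized deterministically as the
weight-combined channel map minus its Otsu threshold (normalized to
[−1, 1]); evolution is gradient descent on the region force with a
Gaussian smoothing step (σ = 0.8 px), and each candidate update is accepted
only if the discrete energy does not increase (backtracking line search
with step halving). The recorded energy history is therefore monotonically
non-increasing by construction; the run stops when the relative energy
decrease falls below 1e−4 (after a 5-iteration burn-in), when the step
collapses below 1e−4, or at 300 iterations (returned with
`converged=False` and a warning). Pixels with φ ≥ 0 are vessel; connected
components under 10 px are removed. Segmentation is fully deterministic
given image and parameters.

ROI cropping uses 0-based pixel coordinates with the origin at the top-left
pixel; containment is decided at pixel centers by the even-odd
(crossing-number) rule, and polygons are validated as simple via shapely.
Metrics are normalized by the ROI pixel count, not the full frame.

## Morphometry

Skeletonization defaults to Zhang–Suen-style iterative thinning
(scikit-image) followed by one topology-preserving thinning pass that
removes the 2×2 staircase blocks Zhang–Suen can leave; a medial-axis
alternative sits behind `method="medial"`. Skeleton "length" is the plain
skeleton pixel count — this is the reading under which VW = VD / VBA equals
mean vessel width in pixels, since VD and VBA then share the ROI-area
normalizer. A Euclidean variant that weights diagonal neighbour steps by
√2 is available via `skeleton_length(..., "euclidean")` for users who want
metric path length; it is not used in VBA by default.

Degenerate inputs: an empty map has VD = VBA = 0 and VW undefined
(`vw_defined=False`, value NaN) — the subset property (skeleton ⊆ mask)
makes VBA > 0 with VD = 0 impossible, so the flag only covers the all-empty
case. An empty ROI is an error, never a silent zero.

## Synthetic data

The generator replaces unavailable in-vivo angiograms and defines the
conditions under which the pipeline is validated.

**Vessel trees.** Trunks sprout from the left image border (the limbal
edge, where corneal ingrowth originates) and advance inward as biased
random walks: per 1-px step the heading receives a Gaussian perturbation
(default sd 0.25 rad) and is clipped to ±1.4 rad of the inward axis;
branches split off with probability 0.06 per step at 70% of the parent
width (widths drawn from 2–5 px). A walker that keeps retracing existing
vessel (three consecutive steps adding no new mask pixel) terminates, which
bounds redundant overlap while still allowing crossings. Growth stops the
moment the rasterized mask reaches the target density, so achieved density
lies in [target, target + 1) percentage points; if the trunk budget is
exhausted first, the generator raises an error naming the achieved density.
The ground-truth mask is by definition the union of discs (diameter = local
width, minimum radius 0.5 px) stamped at every rounded node position — an
invariant the tests re-derive with a brute-force per-pixel oracle — and the
rounded node positions form the ground-truth centerline, a subset of the
mask.

**Rendering.** Vessel and background intensities default to 0.85/0.25; an
optional horizontal ramp and Gaussian blur precede multiplicative gamma
speckle with unit mean and variance 1/shape (shape 20 ≈ moderate OCT-like
speckle; `speckle_shape=None` is the noiseless limit). Output is clipped to
[0, 1].

**Studies.** The default design mirrors the animal experiment the analysis
targets: ten eyes in three arms (anti-VEGF treatment n = 3, saline n = 2,
re-suture n = 5), five weekly visits with injections after week 2. Per-arm
true-density trajectories (means, sd 3%) develop from ~2% to ~31% during
suturing and then diverge: strong regression under treatment (31→10%), mild
decline under saline, persistence under re-suture. Leakage time is
`240 s − 4 s/% · VD + N(0, 10 s)`, floored at 5 s because dye transit
cannot be instantaneous. ICGA-like stages come from a deterministic
monotone rule on density level and trend (clearly growing → 1; ≥ 80% of the
eye's running peak → 2; ≥ 50% → 3; ≥ 25% → 4; else 5; no stage while
essentially avascular, i.e. below 5%). This rule is a documented stand-in
— the real staging is visual and qualitative — chosen so that active stages
carry higher density than regressed ones, which is the structure the
stage-contrast analysis assumes. Cytokines are log-normal with a Gaussian-
copula rank link to true VD (Pearson copula correlation r = 2·sin(πρ/6)
for target Spearman ρ); the default panel uses ρ values of 0.62 (ANG), 0.74
(CXCL-12), 0.14 (CXCL-13), 0.73 (PIGF), −0.01 (IL-8), 0.42 (PDGF-BB), and
two analytes (VEGF-A, CRP) fully below the detection limit to exercise the
exclusion path. Below-LOD censoring masks the configured lower quantile of
an analyte's concentrations as NaN. All randomness flows from one master
seed through per-eye `SeedSequence` substreams.

What the generator does **not** emulate: projection and motion artifacts,
vessel-intensity heterogeneity along a branch, anastomotic loop closure,
depth effects, or observer variability in staging and leakage timing.
Passing tests therefore show correctness of the algorithms under a clean,
known-truth imaging model, not clinical-grade performance on real scans.

## Statistics

Stage contrasts pool stages as {1,2} (reference), {3}, {4,5} and fit
`metric ~ stage_group` with a random intercept per eye by REML (repeated
images of one eye are correlated); when every eye contributes a single
record the random intercept is unidentifiable and the fit falls back to OLS
with a log note. Reported mean differences follow the reference-minus-
comparison convention. Leakage regression is OLS of leakage time on VD,
reporting the signed correlation r and r² separately (an inverse relation
has r < 0 and r² ∈ [0, 1]; the implementation never emits a signed r²).
The cytokine matrix uses Spearman ρ with mid-rank ties, pairwise deletion
of below-LOD values, full exclusion (with a log entry) of analytes that are
entirely undetectable, and flags cells with fewer than 3 complete pairs.
Paired and independent t-tests are two-tailed at α = 0.05; exactly
identical samples return the exact null (t = 0, p = 1) rather than the
indeterminate 0/0. No multiple-testing correction is applied by default,
matching the reporting style of the study design; `holm_adjust` is
available for users who want it.

## Problem sizes and numerical checks

The validation suite runs entirely at desk scale: 128×128 frames, 20 trees
for segmentation overlap (Dice ≥ 0.8 at speckle shape 20), a 30-image
density sweep (5–40%) for rank-recovery of VD, 200 replicate tabular
studies for leakage-slope recovery, and 2000 null simulations for t-test
calibration. These sizes give stable statistics (e.g. Monte-Carlo sd of the
type-I rate ≈ 0.5 points at n = 2000) while keeping a full run in the tens
of seconds. Tolerances quoted in tests (e.g. ±10% on the speckle-variance
moment, 35% on skeleton-vs-centerline agreement, ±15% on width recovery of
a 3-px bar) cover discretization and end effects of thinning, not
implementation slack.

## Known limitations

- The active-contour energy is minimized over a smoothed level-set descent
  with accept/reject steps; it finds a good local minimum from the Otsu
  initialization but is not a global optimizer.
- VW on dense networks overestimates stroke width because crossings merge
  strokes into compound structures with shorter skeletons.
- The γ-neighbourhood regularizer is evaluated on the discrete boundary;
  for γ below 1 px it degenerates to (approximately) a boundary-length
  penalty.
- The mixed-model stage contrast assumes a common residual variance across
  stage groups.
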