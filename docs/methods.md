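# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic data does and does not emulate.

## Synthetic acquisition model

**Geometry.** A raw acquisition is a 4D array `(X, Y, R, Z)` — fast lateral,
slow lateral, B-scan repetitions, depth.  The real system produces
~800×1600×8×500 voxels over a 6×6 mm field and ~2.03 mm depth; that shape is
available via `CohortSpec.full_scale()` (≈5 GB per volume in float32) but the
working default is a desk-scale 128×128×8×96 with the same physical field of
view, so voxel pitch scales accordingly.  The slow axis is 2× oversampled, as
in the real protocol, and is block-averaged during processing.

**Speckle.** Fully developed speckle is modelled as exponentially distributed
intensity.  Static voxels (bulk tissue, and the low-signal glass/air gap above
the tumour surface) receive one exponential draw replicated across the R
repetitions plus Gaussian jitter (σ = 1 intensity unit, against a tissue mean
of 5), giving temporal variance σ².  Vessel voxels are redrawn independently
per repetition from an exponential with mean 40, giving temporal variance
40² — the decorrelation contrast the speckle-variance step detects.  These are
phenomenological choices: no wave optics, attenuation, fringe washout or
depth-dependent SNR is modelled.

**Artifacts.** Salt-and-pepper noise corrupts a configurable fraction
(default 0.5%) of 3D locations by overwriting one random repetition with an
extreme value (300 or 0), which surfaces as isolated hot voxels in the
variance volume.  Motion streaks multiply whole single-repetition B-scan
frames (default 3 per volume) by a gain of 3.  Both are targeted by the
morphological denoising stage.

**Tumour surface and window chamber.** The tumour surface depth map is
piecewise-linear along the slow axis with integer depths at every 20th B-scan
(knots combine a sinusoidal bump of ~5% of the depth extent with a gentle
tilt).  Above the surface sits the avascular glass/air gap (exponential mean
0.3).  Making the surface exactly piecewise-linear at the contour spacing
means the every-20-B-scan contour subsampling used by the VOI stage
reconstructs it *exactly*, which turns "no VOI voxel above the glass" into an
exact invariant rather than an approximation — a deliberate idealisation of
the manual contouring step.

**Registration ground truth.** The tumour footprint is an ellipse defined
analytically in the white-light frame and mapped into the processed OCT
en-face frame by a known similarity transform (scale ≈0.64, rotation 8°,
translation centring the tumour).  Five fiducial pairs are generated exactly
under this transform; the fluorescence image renders the ellipse at intensity
200 inside / 20 outside with Gaussian noise σ = 10, far from the 77/256
binarization threshold on both sides.

**Vessel networks.** Trees grow by biased random walks from randomly seeded
roots: step length U(3, 7) voxels, direction perturbed by Gaussian noise
(reduced depth component, so networks wander mostly en-face), branching
probability 0.12 per step with radius ×0.8 per branching and ×0.985 per
step, root radii U(1.5, 2.4) voxels, extinction below radius 0.7.  Segments
are rasterised as stamped spheres every 0.5 voxels, constrained to ≥2 voxels
below the tumour surface.  Growth stops when the voxelized volume fraction
reaches the target

    density(class, day) = base_density · exp(−decay_class · (day − 14)),

so the realised fraction tracks the analytic expectation to within one
segment's volume.  Defaults: `base_density = 0.08`,
`decay = 0.005/day (10 Gy)` and `0.20/day (30 Gy)`.  The published images
show a qualitative, not quantified, density collapse at 30 Gy by weeks 3–4;
these rates are free parameters chosen once so that the high-dose class falls
below a third of the low-dose density from day 21 onward and is nearly
avascular by day 32, while the low-dose class declines only mildly.  Day 14
is the anchor where both classes coincide — so the earliest time points are
intrinsically ambiguous, which is biologically sensible and keeps the
classification task non-trivial.

**Seeding.** One global cohort seed expands through `SeedSequence` into
independent per-volume streams (network growth, rendering, fluorescence) and
per-run streams (augmentation, weight init, shuffling), making cohorts
reproducible piecewise.

## Processing chain

Temporal variance is computed in float64 with population normalisation
(divide by R); at fixed R = 8 the sample/population distinction is a constant
factor with no effect on classification, and it is exposed as `ddof`.
Variance is computed *before* lateral averaging (averaging adjacent
variances), matching the order of the described acquisition pipeline; the
alternative order would average intensities first.  Denoising is grayscale
opening then closing with a ball of radius 1 voxel followed by a Gaussian of
σ = 1 voxel — the source workflow names the filters but not their parameters,
so the smallest non-trivial sizes are the defaults, and both stages can be
disabled (radius/σ = 0 are exact identities).  An optional slow-axis gain
normalisation ("streak suppression") is off by default since the
morphological stage already removes thin streaks.

## VOI construction

The lateral ROI comes from the fluorescence image: threshold at ≥77 on the
0–255 scale, keep the largest connected component, fill holes (the tumour is
a single closed region; specks must not enter).  The similarity transform is
the closed-form least-squares (Umeyama) fit to the fiducial pairs, no
reflection allowed; masks are warped by inverse mapping with
nearest-neighbour sampling to preserve binarity.  Surface contours are
linearly interpolated along the slow axis with constant extrapolation beyond
the first/last contour.  The VOI is the cylinder over the ROI intersected
with `z ≥ surface`, projected to the full acquired depth.  When moving to the
laterally averaged frame the surface takes the deeper of each averaged line
pair (conservative: never admits air).  Masked volumes are resized by
trilinear interpolation and linearly rescaled to [0, 1]; per-volume maximum
rescaling discards absolute variance units but preserves the spatial density
pattern the classifier uses.

## Datasets

Positive class = low dose (10 Gy), so a true positive is a correctly
identified low-dose volume.  Splits are planned at the mouse level from the
manifest; with 5 mice per class, five runs hold out each mouse exactly once
(8 training, 2 testing mice per run), and leakage is asserted both in tests
and at runtime.  Augmentation samples each transform as an independent
composition of horizontal flip (p = .5), vertical flip (p = .5) and an
en-face rotation (p = .9, angle U(−40°, 90°), linear interpolation, zero
padding, about the depth axis — rotating through the depth-anisotropic axis
would be physically meaningless); identity compositions are rejected and
resampled.  Extra copies are ceiling-balanced across the originals of each
class so every original contributes near-equally to the 100-per-class
training and 16-per-class testing targets.  Test-set augmentation mirrors the
study design and can be disabled (`augment_test=False`) for stricter
evaluation.

## CNN and training

Four conv blocks (16, 32, 64, 64 filters of 3×3×3, stride 1, 'same' zero
padding — padding keeps the 2× halving arithmetic exact for any
multiple-of-16 input), each ReLU-activated and followed by 2×2×2 max pooling
(stride 2); flatten; dense 256 and dense 64, both ReLU; a single sigmoid
output unit.  Implemented in float32 NumPy: convolutions are im2col + BLAS
GEMM, pooling uses explicit argmax bookkeeping for exact gradient routing,
and the loss gradient is taken on logits (σ(z) − y) for numerical stability.
Weights are He-normal for ReLU layers and Glorot-scaled for the head; the
initialisation scheme and batch size (default 2; volumetric batches are
memory-heavy) are unavoidable free choices.  Optimiser: Adam,
step size 10⁻⁴, β = (0.9, 0.999), ε = 10⁻⁸; loss: binary cross-entropy;
10 epochs by default.

Per-epoch training metrics are running averages over minibatches (the
standard fit-loop convention); test metrics are end-of-epoch evaluations.
Both per-epoch prediction vectors are retained in the history, and optional
checkpoints store weights plus predictions, so every recorded loss can be
recomputed independently.  No early stopping is applied: the optimal epoch is
selected post hoc as the earliest test-loss minimum, with a divergence flag
set when the training loss decreases and the test loss increases at every
subsequent epoch (the overfitting signature).  The test set doubles as the
per-epoch monitoring set, as in the original design — a caveat worth naming:
epoch selection on the test set optimistically biases the reported test
accuracy; a three-way split would remove this at the cost of further
shrinking an already tiny cohort.  A predicted probability of exactly 0.5 is
assigned to the negative (high-dose) class; the tie-break is arbitrary but
documented.  Two runs with the same seed on the same machine/BLAS reproduce
identical histories.

## Problem sizes used

The default study configuration is desk-scale: raw acquisitions 128×128×8×96
and a 32³ CNN input for the end-to-end experiments (tests and
`scripts/acceptance.py`), chosen so the full five-run experiment completes in
minutes on a single CPU; 64³ is the package's default CNN input for ordinary
use, and the full 200×200×400 input of the original study is supported by the
same code path (`mask_and_resize` target).  Scaling the input changes the
flattened feature width (and hence the dense-layer parameter count) but no
other architectural property.

## Evaluation

Confusion matrices are averaged element-wise across runs (entries fractional;
quadrants still sum to the common test-set size n = 32); the summary reports
per-run accuracies with mean and *sample* (n−1) standard deviation — the
estimator is a choice, not a given.  Curve plots draw raw per-epoch points;
any smooth guide curves are cosmetic and never used for epoch selection.

## What passing tests do and do not show

The synthetic cohort guarantees that the discriminative signal is a
dose-dependent vascular density trend with realistic nuisance structure
(speckle statistics, artifacts, registration, masking).  It does not emulate
inter-animal biological variability beyond network stochasticity, vessel
calibre remodelling, perfusion dynamics, depth-dependent SNR loss, or
tumour-size change over time.  Recovering the dose effect here therefore
validates the *pipeline* — processing, leakage-free study design,
architecture, training and selection machinery — not the clinical claim that
CNNs separate 10 from 30 Gy in real animals; headline accuracies on real
data cannot be reproduced without the original (non-public) images.

## Degenerate inputs and numerical conventions

Variance requires R ≥ 2 and rejects NaN; lateral averaging requires a
divisible slow axis and names the axis in the error; a single surface contour
yields a constant surface with a warning; empty post-threshold fluorescence
masks, degenerate fiducials (coincident points), heterogeneous tensor shapes,
sub-16 CNN input extents and non-binary labels all raise with specific
messages; non-finite training loss aborts with the offending batch.  All
volume indices are 0-based `(X, Y[, R], Z)`; epochs are reported 1-based.
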