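# Methods

This note documents the models and procedures implemented in mammofuse, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that affect results.

## Preprocessing

An ROI enters as a 2-D nonnegative integer array on a 16-bit gray scale
(DICOM rescale slope/intercept applied at load time; MONOCHROME1 images are
inverted so bright always means dense tissue). Five steps follow:

1. **Background crop.** The minimal bounding box of pixels strictly above
   `threshold × max(pixels)` is kept. The default threshold is 0 (any strictly
   positive pixel is content); a small fraction such as 0.05 is appropriate
   when the background carries detector noise.
2. **Intensity normalization.** `(X − min) / (max − min)` maps the ROI onto
   [0, 1]. A constant ROI would divide by zero; it maps to all zeros with a
   warning. This keeps batch pipelines total — a flat patch carries no texture
   information anyway.
3. **Size normalization.** The longer side is scaled to 224 with bilinear
   interpolation (no anti-aliasing prefilter, so constant regions stay exactly
   constant and no value leaves the input hull after clipping to [0, 1]); the
   result is centered on a 224×224 zero canvas. Centering avoids a systematic
   spatial bias in convolutional features; the scale factor, pad offsets and
   content rectangle are recorded so downstream code can mask out padding.
4. **Cohort split.** Seeded random split at ROI level (default train fraction
   744/988 ≈ 0.753, stratified by class). ROI-level splitting can place two
   views of one patient on opposite sides; a `by_patient` mode keeps each
   patient's ROIs together (implemented as a plain patient-level shuffle,
   without stratification).
5. **Dihedral augmentation.** The seven non-identity symmetries of the square
   (rotations by 90°/180°/270°, horizontal flip, and flip combined with each
   rotation). Original + augmented therefore form the full 8-element orbit.
   Augmentation is used for network training, not for SVM feature tables.

## Hand-crafted features (455)

Fixed order and sizes: histogram 9, Hu 7, GLCM 56, GLGCM 15, GLDS 4, GLRLM 44,
LBP 256, GMRF 4, Gabor 60. The decomposition is part of the public contract;
feature names (`family.descriptor[.direction|.scale_orientation_stat]`) are
stable across versions. All statistics are computed on the content rectangle
only — the zero frame added by padding would otherwise dominate co-occurrence
counts. All entropies are in bits.

Conventions that matter:

- **Quantization.** 64 uniform gray levels over the content's [min, max] for
  GLCM/GLDS/GLRLM; 16 gray × 16 gradient levels for GLGCM. These are standard
  radiomics settings that keep 64×64 co-occurrence matrices well populated on
  a 224² canvas.
- **GLCM.** Symmetric, normalized co-occurrence at distance 1 in four
  directions; 14 Haralick descriptors per direction, direction-major order.
  Degenerate marginals (constant content) define correlation and the maximal
  correlation coefficient as 0 so every output stays finite.
- **GLGCM.** Joint histogram of quantized intensity and quantized Sobel
  gradient magnitude; 15 classical descriptors (gradient dominance, asymmetry,
  means/variances, correlation, entropies, inertia, inverse difference
  moment), with 1-based indices in the dominance weights.
- **GLRLM.** Maximal constant-intensity runs in four directions; 11
  descriptors per direction with 1-based gray level and run length. The
  implementation shears diagonals into rows and counts runs vectorized; tests
  verify it against naive run enumeration.
- **LBP.** Classic 8-neighbor codes at radius 1, neighbors read clockwise from
  the top-left with the first neighbor in the most significant bit; the tie
  rule is neighbor ≥ center → 1, so constant regions code 255 everywhere
  rather than depending on floating-point noise. Interior content pixels only.
- **GMRF.** The four symmetric interaction coefficients (horizontal, vertical,
  diagonal, anti-diagonal) of a second-order Gaussian Markov random field,
  estimated by least squares of each interior pixel on its neighbor-pair sums
  (the conditional-mean regression, which is consistent for this model).
  Near-singular normal equations (condition number > 1e10, e.g. a pure ramp)
  fall back to a ridge-regularized solve with a warning.
- **Hu moments.** Intensity-weighted (no binarization), computed on the full
  canvas, reported as sign(h)·log10|h| for numeric stability.
- **Gabor bank.** 4 wavelengths (4, 8, 16, 32 px) × 5 orientations (0°–144°
  in 36° steps), bandwidth 1 octave, aspect ratio 0.5; mean, standard
  deviation and energy of the response magnitude over content, scale-major
  order. Filtering uses circular FFT convolution with kernel transforms cached
  per image shape; the wrap-around convention makes constant images produce
  exactly constant responses.

## Deep features

The fusion architecture: two convolutional backbones pooled separately
(512-channel VGG16-style and 2048-channel Inception-V3-style), global max
pooling, concatenation to 2560, then FC layers 2560 → 2048 → 1024 → 2 with
ReLU, dropout (default rate 0.5) and a softmax output. The 1024-d activation
of the second FC layer is the deep feature. A single-backbone baseline
(512-pool → FC 1024 → FC 2, global *average* pooling) is provided as a
comparison arm; the pooling difference between the two arms is deliberate and
recorded as an upstream design inconsistency, not an interpretation.

The implementation is pure numpy. Backbones are fixed seeded random-weight
conv stacks exposing exactly the contract dimensions (`weights_origin =
"tiny_test"`); they act as frozen feature extractors, and training updates the
FC head only, by hand-written backprop with SGD — momentum 0.9, weight decay
5×10⁻⁴, default 200 epochs at learning rate 10⁻⁴, cross-entropy loss.
Requesting `weights_origin="pretrained"` raises an explicit error: no
published backbone weights are bundled, and silently substituting random
weights would misrepresent the model. `frozen_prefix_layers` (default 12) is
retained as configuration metadata for checkpoint-based workflows. Random
projections through ReLU conv stacks preserve linear separability well enough
that the trained head reaches perfect accuracy on separable toy data, which is
what the contract tests exercise.

## Feature selection

mRMR with equal-frequency discretization (4 bins; rank-based, so any strictly
monotone transform of a feature leaves the selection unchanged) and plug-in
mutual information in bits. The greedy objective is relevance − mean
redundancy (MID, the reference default); the quotient form MIQ is available.
Ties break toward the earlier column, making selection fully deterministic.
The hand-crafted block is ranked to k = 30 and the deep block independently to
k = 27 (the per-block counts are configuration, not computed quantities);
selection is always fitted on training rows only. Joint ranking across blocks
is available behind a flag.

## Classifier

Clinical covariates are used as ordinal numeric codes (not one-hot): the
shape/margin/composition scales are ordered severity scales, and the source
coding is explicitly numeric. The fused vector is 27 deep + 30 hand-crafted +
5 clinical = 62 values, min-max scaled per feature by training-set extrema;
test-time values are clipped to [0, 1] so the SVM input domain stays bounded.
The SVM is linear-kernel; C is selected from {0.01, 0.1, 1, 10, 100} by
stratified 10-fold cross-validated accuracy with ties resolved toward smaller
C (ascending grid, strict improvement). Scalar metrics threshold the decision
score at 0 — the classifier's native boundary — rather than a Youden-optimal
cut; a threshold argument exists for sensitivity analyses.

## Evaluation

Positive class = malignant. Sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy, precision TP/(TP+FP), and F1 (the harmonic mean; no β weighting).
Undefined ratios (no positive predictions, single-class cohorts) are reported
as NaN with a flag, never silently zeroed. The ROC curve is a threshold sweep
over the unique scores with ties stepping diagonally; the trapezoidal AUC then
equals the tie-corrected Mann–Whitney statistic exactly, which the tests check
by brute-force pair counting. DeLong's test uses the fast placement-value
covariance estimate and a two-sided normal approximation for the paired AUC
difference; identical score vectors give z = 0, p = 1 by convention.

## Synthetic data

The generator emulates the structure a mass-classification pipeline must
exploit, not mammographic physics:

- **Morphology.** Star-convex boundaries r(φ): an ellipse (random axis ratio
  0.6–1.0) modulated by low-frequency harmonics. Benign masses use a small
  wobble amplitude (0.04) and no spicules; malignant masses use a larger
  wobble (0.18) plus 4 + Poisson(8) Gaussian-profile radial spicules about
  0.55 radii long. Radii are Normal(70, 12) px benign and Normal(60, 12) px
  malignant on a 320² canvas.
- **Texture.** A unit-variance Gaussian random field (white noise smoothed at
  the class correlation length: 6 px benign, 1.5 px malignant) scaled by a
  5000-count amplitude with a 1.4× malignant contrast boost, on a 26000-count
  base with radial falloff; additive Normal(0, 400) noise inside the mass;
  background exactly zero. Values are clipped to the 16-bit range.
- **Clinical covariates.** Class-conditional categoricals — malignant:
  P(shape=irregular) = 0.7, P(margin=spiculated) = 0.5; benign:
  P(shape∈{round, oval}) = 0.8, P(margin=clear) = 0.5 — with denser breast
  composition and older age (Normal(58, 10) vs Normal(45, 10), truncated to
  [20, 80]) in the malignant class. Mass size equals the ROI diagonal of the
  generated patch.
- **Structure.** ROIs are paired two-per-synthetic-patient (CC and MLO views)
  so patient-level splitting is exercisable. Everything derives from one
  integer seed; regeneration is bit-identical.

`SyntheticSpec.null()` sets the malignant distributions equal to the benign
ones — the no-signal control under which held-out AUC must sit at chance.

What passing tests on this generator demonstrate: that each stage computes its
contract correctly, that the texture families detect the boundary and
correlation-length differences they are designed for, and that the pipeline
neither leaks test information (null AUC at chance) nor destroys signal
(default AUC ≥ 0.90). What they do not demonstrate: performance on real
mammograms — the generator has no breast parenchyma, no imaging physics, no
BI-RADS density realism, and its class differences are cleaner than clinical
ones, which is why held-out metrics saturate at 1.0 on the default spec.

## Problem sizes and statistical checks

The end-to-end acceptance runs use 100 ROIs per class with a 70/30 split —
large enough that a held-out AUC ≥ 0.90 bound and a chance-level null are
meaningful, small enough to run routinely. A single 60-sample held-out AUC has
a sampling SD near 0.08 under the null, so the chance band [0.4, 0.6] is
asserted on the mean of three seeded replicates. DeLong's type-I error is
calibrated over 1000 null simulations at n = 100 (expected rejection rate 0.05
at α = 0.05, accepted within [0.03, 0.07]); GMRF recovery is checked on
128² Gibbs-sampled fields (tolerance ±0.05); mutual information of independent
variables at n = 1000 with 4 bins must stay below 0.05 bits (the plug-in bias
is ≈ (r−1)(c−1)/(2N ln 2) ≈ 0.007 bits).

## Known limitations

- The deep stage's backbones are random-weight stand-ins with the contract
  dimensions; transfer learning from pretrained weights requires supplying a
  framework checkpoint out of band and is not exercised here.
- Whole-mammogram detection/segmentation, pectoral-muscle removal and
  enhancement (e.g. CLAHE) are out of scope; inputs are already-cropped
  rectangular ROIs.
- No confidence intervals on single AUCs, probability calibration, or
  class-imbalance handling (the intended cohorts are balanced).
- mRMR selects on the full training cohort, not within CV folds; the
  cross-validation therefore tunes only the SVM penalty.
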