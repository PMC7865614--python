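# Methods

## Problem and model

The package quantifies left–right hemispheric asymmetry in a single 2D
brain slice and uses it as a biomarker for staging dementia. The working
assumption is that a healthy slice carries an axis of reflective symmetry
through the brain's center; disease-related atrophy breaks that symmetry in
a stage-dependent way (more symmetric than normal in early mild cognitive
impairment, much less symmetric in Alzheimer's disease). The analysis
proceeds in the order: standardization → midline alignment → mirror
subtraction → texture/bag-of-features description → cross-validated binary
classification.

## Preprocessing

Inputs are 8/16-bit grayscale or RGB rasters (RGB collapsed by channel
averaging — MRI is intrinsically scalar, so the three channels of a
display-oriented file are redundant). Standardization is bilinear resizing
to 256×256 (pixel-center-aligned sampling, edge clamp) followed by min-max
rescaling to [0, 255]; a constant image maps to all zeros. Min-max was
chosen over z-scoring because every later stage (binarization thresholds,
the threshold band, 8-bit map semantics) reasons on the 0–255 scale.

Skull stripping retains pixels inside a configurable intensity band
`[lower, upper]` (defaults 60–200) and then keeps only the largest
8-connected in-band component, discarding skull arcs and islands. This is a
deliberately simple, fully automatic stand-in for interactive thresholding;
the band is configuration, not a constant, and any dedicated brain-extraction
tool can be substituted upstream.

## Midline alignment

The brain mask (Otsu threshold on the nonzero histogram, or a fixed
threshold) gives an unweighted centroid — the intensity-weighted center of
mass is available by flag — which is translated to the geometric image
center `((H−1)/2, (W−1)/2)` with bilinear interpolation. The rotation that
maximizes mirror symmetry is found by exhaustive grid search over
[−15°, +15°] at 0.5° steps (both configurable), minimizing the mean squared
difference between the rotated image and its vertical mirror over the union
support of nonzero pixels. Ties break toward the smallest |angle|, then
toward the negative angle, so a circularly symmetric input yields exactly
0°. The exhaustive grid is intentional: the objective is non-convex in the
presence of lesions, and a deterministic search keeps every run
reproducible at the cost of ~61 rotations per image (≈0.25 s at 256×256).
Rotation uses bilinear interpolation about the image center with zero fill.

On phantoms with |shift| ≤ 10 px, |angle| ≤ 10° and noise σ = 2, the stage
recovers the pose to well within 1 px and one 0.5° grid step (validated on
50 random phantoms; the suite asserts a ≥95% hit rate, observed 100%).

## Asymmetry map

The map is the two-way saturating hemispheric subtraction
`D = clip₀(I − M) + clip₀(M − I)` with `M` the vertical mirror of the
aligned slice. Under real arithmetic the naive sum `(L − R) + (R − L)` is
identically zero; with 8-bit floor-at-zero semantics each term keeps one
sign of the difference, and the sum equals `|I − M|` elementwise on the
full grid — zero exactly where the hemispheres match. The implementation
computes the clipped form and the test suite verifies the equivalence with
a brute-force saturating-arithmetic oracle on random integer rasters.

## Statistical features

Each map yields the fixed, ordered 10-vector (MSE, Mean, Std, Entropy, RMS,
Variance, Smoothness, Kurtosis, Skewness, IDM):

* **MSE** is the only statistic computed without a wavelet transform: the
  mean squared difference between the aligned slice and its own mirror.
* The other nine are computed on the approximation subband of a single-level
  2D Haar (db1) DWT of the map. Haar at level 1 is the default because it is
  the simplest orthogonal wavelet with exact small-case oracles (a constant
  image scales by 2 per level); family and level are configurable.
* Moments use population (biased) estimators and non-excess kurtosis
  (Gaussian → 3), making Variance = Std² and RMS² = Mean² + Variance exact
  identities.
* Entropy is Shannon entropy (base 2) of the 256-bin histogram of the
  subband min-max rescaled to [0, 255]; it lies in [0, 8] bits.
* Smoothness is 1 − 1/(1 + σ²) with σ² the variance of the subband rescaled
  to [0, 1] (the Gonzalez–Woods texture convention), so it lies in [0, 1).
* IDM is Σ P(i,j)/(1 + (i−j)²) over a normalized symmetric 256-level GLCM
  at offset (0, 1), bounded in (0, 1] with 1 for a constant image. An
  unnormalized-GLCM variant is available as a compatibility flag for
  workflows that report raw co-occurrence counts.

A perfectly symmetric slice gives the degenerate all-zero map; the contract
is: entropy, smoothness, all moments 0; kurtosis/skewness undefined and
reported as 0 with a warning; IDM 1.

Published per-image examples of such 10-vectors are not internally
consistent under any single set of standard conventions (e.g. a printed Std
whose square is not the printed Variance, an IDM far above 1), so the
canonical formulas above are adopted and documented rather than
reverse-engineered; the fixed ordering of the vector is preserved.

Dataset-level summaries: per-feature min-max normalization to [0, 1]
(constant features map to 0), per-class feature means, and a Pareto
ordering of per-class total mirror-MSE with cumulative percentages.

## Bag of features

Keypoints come from a Determinant-of-Hessian blob detector (σ ∈ [2, 12]);
images with fewer than 8 blobs fall back to a dense grid at fixed scale so
every image stays encodable. Each keypoint is described by a 64-dim vector:
the window of half-size 10σ is resampled to a 16×16 grid of
Gaussian-smoothed gradient samples, split into 4×4 subregions, each pooled
into (Σdx, Σ|dx|, Σdy, Σ|dy|), and the vector L2-normalized — the classical
SURF descriptor layout, computed with dense gradients rather than box
filters. The strongest 80% of keypoints by scale-normalized Laplacian
response are retained. The vocabulary is K-Means (k-means++ init, fixed
seed; k = 500 by default, smaller for small cohorts since k may not exceed
the descriptor count) and each image is encoded as the L1-normalized
nearest-center occurrence histogram; a descriptor-free image encodes as the
uniform histogram with a warning. Descriptors are computed on the asymmetry
map (not the original slice): the map is where the disease signal was
segmented, so its local structure is the feature source.

By default the pipeline fits one unsupervised codebook on the whole corpus
(no labels are involved). For strictly leak-free protocols
`cross_validate` accepts a per-fold feature builder so fold-dependent
encodings are fitted on training folds only; the suite verifies the hook
with a canary feature that carries the label in test folds only.

## Classification protocol

Eight models with fixed hyperparameters, no tuning: Gaussian Naive Bayes;
linear discriminant analysis; SVMs with linear, quadratic, cubic and
medium-Gaussian kernels (box constraint 1, inputs standardized, kernel
scale "auto" except the Gaussian's manual 32); 1-NN Euclidean and 10-NN
cosine (standardized). "Kernel scale s" follows the divide-predictors-by-s
convention — poly kernels read ((x/s)ᵀ(y/s) + 1)^d, the Gaussian
exp(−‖x−y‖²/s²) — and "auto" is realized as the median of nonzero pairwise
training distances (the median heuristic), computed inside each training
fold.

Evaluation is 10 runs of stratified 10-fold cross-validation, folds
reshuffled per run from seeds derived from the master seed.
Standardization lives inside the model pipeline, so it is fitted on
training folds only. The positive class is the more severe diagnosis of
each pair (AD > EMCI > NC); accuracy, sensitivity and specificity are
computed per fold and averaged over all folds of all runs (the reported
spread is the std across per-run means — whether to average folds or pool
confusions was an open choice; fold-averaging is used and logged). ROC
curves pool the out-of-fold scores of all runs (SVM signed margins, KNN
vote fractions, NB/LD posteriors); AUC is the trapezoid area over the
threshold sweep, which equals the rank-average Mann–Whitney statistic
U/(n₁n₂), verified against a pair-counting oracle.

## Synthetic phantoms

A phantom is a 256×256 slice built from hard-edged ellipse masks: skull
ring at intensity 240, dark CSF gap (25) separating it from the tissue
ellipse (base 130 with smooth random texture of amplitude ≤22, symmetrized
exactly by averaging with its own mirror), and a symmetric ventricle pair
at 70. Intensities are chosen so tissue (including ventricles and lesions)
stays inside the default 60–200 skull-strip band while skull, gap and
background fall outside it — making the surviving-pixel count of the strip
stage exactly the truth tissue-mask area. All asymmetry is injected as
unilateral truncated-Gaussian lesions (σ = radius/2, cut at 3σ, footprint
kept clear of the midline), so the ground-truth asymmetry of a phantom is
exactly its lesion content. Pose (rotation then shift, bilinear) is applied
after rendering and noise after pose, so alignment must cope with noisy
mirror residuals, as on real scans.

Class defaults encode the clinical ordering: lesion amplitudes EMCI = 2,
NC = 6, AD = 14 intensity units (asymmetry dips in EMCI, rises strongly in
AD), 3 lesions of radius 8 px, pose uniform within ±8 px / ±8°, noise
σ = 2. At these defaults the class-mean mirror-MSE ordering AD > NC > EMCI
emerges with a margin of roughly eight standard errors at 30 images per
class, and the suite checks it across 100 independently seeded cohorts.

What the phantoms do *not* emulate: anatomy (gyri, tissue-class contrast),
MR physics (bias fields, Rician noise, partial volume), inter-subject
variability of brain shape, and bilateral-but-asymmetric structures.
Passing tests therefore demonstrate the correctness and stability of the
pipeline's mechanics — alignment, map extraction, feature identities,
harness behavior — not clinical accuracy on real MRI.

## Problem sizes and numerical choices

The validation suite and the reproduction script run cohorts of 30 images
per class (and an 8-per-class cohort for the bit-determinism rerun), a
bag-of-features vocabulary of k = 32 for simulated cohorts, and 10×10-fold
cross-validation — sizes chosen so a full desk-scale replication completes
in minutes on one CPU while keeping every statistical margin wide. The
"well-separated" cohort used to exercise the classifier harness lowers the
noise to σ = 0.5 so that lesion asymmetry sits an order of magnitude above
the noise floor.

Other numerical conventions: coordinates are 0-based (row, column); for
even width the mirror axis lies between columns W/2−1 and W/2; rotation is
counter-clockwise positive about the geometric image center; interpolation
is bilinear with zero fill everywhere; intensities are clipped to [0, 255]
after every resampling step; degenerate inputs (blank images, empty masks,
empty threshold bands, single-class labels) raise typed errors naming the
stage.

## Known limitations

* 2D only: no midsagittal-plane fitting or 3D skull stripping.
* The rotation search is global but quantized at the grid step; sub-step
  refinement is not attempted.
* Skull stripping assumes the brain is the largest in-band component;
  severe pathology or cropped fields of view can violate this.
* The corpus-level codebook is fitted once per run for speed; use the
  per-fold builder for strictly leak-free bag-of-features evaluation.
* Classifier scores on small cohorts (n = 60 per pair) carry fold-level
  variance of a few percentage points; reported means average 100 folds.
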