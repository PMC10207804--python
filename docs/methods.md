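# Methods

`radcascade` implements a complete preoperative CT-radiomics pipeline for
classifying pediatric neuroblastic tumors into ganglioneuroma (GN),
ganglioneuroblastoma (GNB), and neuroblastoma (NB): geometry harmonization,
3D radiomic feature extraction, univariate screening plus
maximum-relevance–minimum-redundancy (mRMR) feature selection, and a
two-stage LASSO cascade, together with a synthetic cohort generator that
makes the whole chain testable without patient data.

## Geometry and discretization

Volumes and masks are read from NIfTI or NRRD (SimpleITK), resampled onto a
common grid of 0.5 × 0.5 × 5 mm (trilinear for the image, nearest neighbor
for the mask, threshold 0.5, nearest-neighbor extrapolation at the grid
border so constants survive resampling exactly). Gray levels are fixed-bin-width
re-binned with width 20 intensity units. Bins are anchored at the ROI
minimum — `level = floor((I − min_ROI)/w) + 1` — which makes all texture
features exactly invariant under intensity shifts and therefore testable;
toolkits that anchor at absolute zero will produce different level maps for
the same image. Each image (original and each wavelet sub-band) is
discretized independently.

## Feature set (851)

* 14 shape features from the mask alone. The surface is the 0.5 level set of
  the Gaussian-smoothed (σ = 0.8 voxels) binary indicator, triangulated with
  marching cubes in voxel space and scaled by the spacing in float64. The
  anti-aliased surface tracks the true boundary far better than the
  staircase mesh of the raw mask (digital-ball sphericity 0.99 vs 0.92); the
  cost is a mild volume bias on very thin masks, and masks too small for the
  smoothed peak to reach 0.5 fall back to the binary mesh. Axis lengths are
  4·√eigenvalue of the physical voxel-center covariance.
* 18 first-order statistics; entropy/uniformity use the fixed-bin-width
  histogram; skewness/kurtosis use population moments with the constant-input
  convention 0; kurtosis is non-excess (Gaussian → 3).
* 75 texture features per image: GLCM (24), GLRLM (16), GLSZM (16), GLDM
  (14), NGTDM (5). GLCM and GLRLM are computed per direction over the 13
  unique Chebyshev-distance-1 offsets and the feature values averaged
  (matrices are not merged). GLSZM zones are maximal 26-connected
  equal-level components. GLDM uses the 26-neighborhood with dependence
  tolerance α = 0; a voxel's dependence is 1 + its number of equal-level
  in-mask neighbors, so dependence indices start at 1 and small-dependence
  emphasis never divides by zero. NGTDM neighborhood means exclude
  out-of-mask voxels; only voxels with ≥ 1 valid neighbor contribute.
* 8 wavelet sub-bands from one level of separable undecimated filtering
  along x, y, z with symmetric boundary extension; sub-band letters follow
  axis order. The default filter is the orthonormal 2-tap Haar pair, chosen
  because its high-pass exactly annihilates constants, which yields exact
  unit tests; any PyWavelets filter name can be configured. The filter bank
  is implemented directly (correlate1d per axis) rather than via
  `pywt.swtn`, whose even-shape/periodization constraints conflict with
  shape-preserving filtering of arbitrary grids. Each sub-band contributes
  18 first-order + 75 texture features.

Total: 107 original + 8 × 93 = 851, the unique standard composition
consistent with that printed count.

Degenerate single-level ROIs resolve to finite conventions (GLCM
Correlation = 1, Imc1 = 0, Imc2 = 0, MCC = 1, NGTDM coarseness capped at
1e6) so downstream selection never sees NaNs.

## Feature selection

Subjects are split 3:1 into training and validation, stratified per class
(validation count = round-half-up of n/4, minimum 1); with class sizes
14/24/65 this gives validation 4/6/16 and training 10/18/49. Each radiomic
feature is screened across the three classes on training rows only: one-way
ANOVA when Shapiro–Wilk accepts normality (p > 0.05) in all three classes,
Kruskal–Wallis otherwise; survivors are the features with raw p < 0.05 (no
multiple-testing correction, deliberately). Age and gender bypass the screen
and join the candidate pool directly.

mRMR uses the mutual-information-difference objective
I(f; y) − (1/|S|)·Σ_{s∈S} I(f; s) with greedy forward selection of the top
10. Continuous candidates are discretized to 4 equal-frequency bins; labels
are used as-is; ties break lexicographically on the feature name, making the
ranking deterministic. The reported importance is the objective value at the
moment of selection. The MID variant with discrete MI was chosen as the
original formulation of the algorithm; MIQ would be a one-line change.

## Cascade classifier

Classification proceeds through two binary stages: GN vs non-GN on all
training subjects, then GNB vs NB on the non-GN training subjects only. Each
stage is an L1-penalized *linear* least-squares model on a 0/1 response —
not logistic regression — matching the least-squares-coefficient /
cross-validated-MSE formulation of the modeled protocol; most radiomics
studies use logistic LASSO, so this divergence is deliberate and documented.

Per stage, features are normalized by a two-pass robust z-score learned on
that stage's training subjects: mean/SD, exclude |z| > 3, recompute. Note
that in a sample of n points a single outlier's |z| cannot exceed
(n−1)/√n, so exclusion only triggers in reasonably large samples; a
zero-variance feature maps to 0. The solver is cyclic coordinate descent
with soft-thresholding on the Gram matrix of the centered design
(numba-compiled), converged at max coefficient change < 1e-7, warm-started
along a descending path of 100 log-spaced λ values from λ_max (the smallest
λ with all-zero coefficients) down to 1e-4·λ_max. λ is selected by minimum
5-fold cross-validated MSE with folds stratified by the stage's binary label
(10 GN training subjects make unstratified folds degenerate); ties resolve
to the largest λ.

The decision threshold on the continuous stage score is chosen on training
data by maximizing Youden's J along the training ROC (largest threshold on
ties); a fixed 0.5 cut is available in the configuration since the operating
point of the original protocol is not stated. Prediction short-circuits:
stage-1 score ≥ threshold → GN; otherwise stage 2 decides GNB vs NB.

## Evaluation

AUC is the tie-corrected Mann–Whitney statistic divided by n₁·n₀ (equal to
the trapezoidal area under the empirical ROC, which is asserted in tests).
Stage metrics condition on the true binary task — stage 2 is evaluated on
subjects whose true class is GNB or NB — while end-to-end cascade errors
appear in the 3×3 confusion matrix (rows = predicted, columns = true).
Both plain overall accuracy (trace/total) and macro-averaged recall are
emitted, since "balanced accuracy" is ambiguous in the source material.

## Synthetic cohorts

Each subject is an ellipsoidal tumor (semi-axes uniform in 5–11 voxels) on a
48³ grid at 0.5 × 0.5 × 5 mm, over a noisy background (−40 ± 10 HU-like
units). In-mask intensity = base (45) + a spatially correlated Gaussian
field + independent voxel noise (SD 8). The correlated field is white noise
smoothed with an isotropic Gaussian kernel of the class's correlation
length and rescaled so its *in-mask* SD equals the class's heterogeneity
amplitude — without the in-mask rescaling, long correlation lengths leave
almost no variance inside a small tumor and voxel noise swamps the signal.

Class defaults follow the modeled cohort: sizes 14/24/65; ages in months
from truncated normals 7.36 ± 3.77 (GN), 4.38 ± 2.61 (GNB), 2.38 ± 2.49
(NB) (the units are taken as printed and treated as opaque location/scale
parameters, even though months are implausibly small for this disease);
male probabilities 8/14, 13/24, 38/65. Texture moves from coarse and mild
(GN: correlation length 4.0 voxels, heterogeneity 20) through intermediate
(GNB: 2.2 / 32) to fine and strong (NB: 1.1 / 45), so the separating signal
lives exactly in the GLCM correlation/Imc and GLSZM zone-size families that
drive the real classifier, plus the age distribution. Everything is
determined by a single seed via named sub-streams.

What the generator does *not* emulate: anatomy, contrast phase, scanner
artifacts, irregular tumor shapes, inter-scanner variation, or any realistic
link between texture and pathology. Passing tests therefore demonstrate that
the pipeline recovers class structure *planted in the feature families the
method relies on* — a correctness property of the implementation, not
clinical evidence.

## Problem sizes and numerical choices

The recovery study runs 10 seeds of a 130-subject cohort (20/30/80) on 48³
grids; a full seed (extraction + both cascades) takes well under a minute on
one CPU, and the 103-subject headline run in `scripts/acceptance.py`
completes in under a minute. Texture oracles are verified on 6×6×3 ROIs
where brute-force enumeration is exact. Tolerances: texture vs oracle 1e-10;
LASSO closed forms 1e-8 (soft-threshold) and 1e-6 (OLS limit); coordinate
descent tolerance 1e-7.

## Known limitations

* Shape features use an anti-aliased surface; volumes of very thin or tiny
  masks are biased low relative to the voxel count.
* The robust normalization's outlier pass is inert for very small samples
  (see above) — a faithful property of the two-pass z-score rule.
* The mRMR variant (MID, 4-bin equal-frequency MI) and the wavelet filter
  are explicit design choices where the modeled protocol is silent;
  alternatives are configurable but untested against any reference cohort.
* Published performance numbers from the original clinical cohort are not
  reproducible here because those data are private; the pipeline's
  validation metrics on synthetic cohorts reflect the planted class
  separation only.
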