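# Methods

This note records the models, conventions and numerical choices the
package implements, the parameters that matter, and what the synthetic
validation does and does not establish.

## ROI handling and quantization

All features are computed on the tight bounding-box crop of the nodule
mask. Voxels inside the box but outside the mask never contribute:
co-occurrence pairs, runs, zones and neighborhoods that would cross an
out-of-mask voxel are discarded (not bridged), and before any
convolution the out-of-mask voxels are replaced by their nearest
in-mask value (Euclidean distance in physical units) so filter
responses near the boundary are not contaminated by background air.
Arrays are indexed `(x, y, z)`, 0-based; masks binarize at 0.5 on load.

Gray-level quantization is equal-width binning over the in-mask
min–max range. A constant region maps wholly to code 0. With integer
codes `0..L-1` re-quantized at the same `L` the mapping is the
identity (idempotence), and it is order-preserving for any input.
Defaults: 256 levels for GLCM and RLM, 64 for GLSZM and NGTDM (denser
matrices for small nodules; all four are knobs of the extractor and
the `extract` subcommand). No intensity clipping/windowing is applied
before extraction, and no resampling is performed by default — the
extractor assumes a single acquisition resolution; volumes with
heterogeneous spacing should be resampled upstream.

## The 16-statistic summary

The same statistic set summarizes the raw ROI and every filtered
response: min, max, median, peak (mode of a 64-bin histogram, bin
center), mean, SD (population), coefficient of variation, RMS,
skewness, excess kurtosis, energy (unnormalized sum of squares — RMS
carries the normalized version), histogram entropy (base 2),
uniformity (sum of squared histogram probabilities), range, and the
GLCM contrast and homogeneity of the region re-quantized to 32 levels
(distance 1, 13 directions). Degenerate limits are fixed by
convention and exercised in tests: zero-variance samples have
skewness = kurtosis = 0, entropy 0, uniformity 1; CV is 0 when the
mean is 0 (common for zero-mean filter responses); a region without
any valid voxel pair takes the constant-image texture limits
(contrast 0, homogeneity 1).

## Intensity-volume histogram and shape

`Ix` is the largest intensity such that at least x% of the ROI volume
lies at or above it (the imaging analogue of dose-volume-histogram
reporting); `Vx` is the volume fraction at or above
`min + x% · range`. Both use the decile grid {10, 30, 50, 70, 90}.

Shape: volume is voxel-count × voxel volume; surface area comes from a
marching-cubes mesh of the zero-padded mask at level 0.5;
sphericity = π^(1/3)(6V)^(2/3)/A, compactness1 = V/(√π·A^{3/2}),
compactness2 = 36πV²/A³ (= sphericity³ identically). The maximum 3D
diameter is the largest pairwise distance between voxel *corners* of
the surface voxels (corner points make the single-voxel diameter equal
the voxel diagonal rather than zero); a convex-hull reduction keeps
the pairwise scan tractable for large nodules.

## Filter banks

* **Laws.** The separable length-3 family L3 = (1,2,1), E3 = (−1,0,1),
  S3 = (−1,2,−1); a 3-letter id applies one 1D kernel per axis in id
  order, giving 27 3D kernels. E3/S3 are zero-sum, so constants map to
  exactly 0; the all-level kernel LLL has gain 4³ = 64. Responses are
  summarized directly (no texture-energy macro-windowing).
* **Wavelet.** One-level 3D discrete wavelet decomposition, Haar by
  default (exact arithmetic in tests; the family is a knob). The 8
  subbands are named by per-axis low/high (LLL…HHH) and mapped back to
  patch geometry by 2× repetition and cropping so the mask applies.
* **LoG.** An explicitly sampled anisotropic Laplacian-of-Gaussian
  kernel (σ in mm converted to voxels per axis through the spacing;
  support 4σ, minimum radius 1 voxel), shifted to exactly zero mean so
  affine images map to zero response up to float rounding (|response|
  ≲ 1e−13 on constants; tests assert ≤ 1e−9). Applied by FFT
  convolution over symmetric padding. Scales: σ ∈ {1,…,6} mm, a knob.
  A σ with sub-voxel support on every axis is rejected.

Boundary handling is symmetric (mirror) padding everywhere.

## Matrix features

Directional statistics use the 13 unique non-antipodal offsets with
components in {−1,0,1} at distance 1 voxel. The GLCM accumulates
symmetric pair counts over the 13 offsets and normalizes to a
probability matrix (summing counts before normalizing equals averaging
per-direction matrices). The RLM counts maximal same-code runs per
direction, summed over the 13 directions and normalized by total run
count; the run percentage divides by `13 · n_voxels`. The GLSZM uses
26-connected zones of equal code. The NGTDM uses 26-neighborhood
means restricted to in-mask voxels; the coarseness denominator is
guarded by ε = 1e−6 (constant images cap at 1e6). Gray levels enter
all matrix-feature formulas 1-based. The 26 co-occurrence features
and the 11 run-length/size-zone features follow the canonical
Haralick/Galloway lists recorded per name in the feature registry
(`noduleomics registry` exports name → definition as CSV).

Fractal dimension: the in-mask set at or above `min + f · range` for
f ∈ {10%,…,80%} is box-counted at sizes {2,4,8,16} (clipped to the
patch extent; patches are padded to ≥ 4 voxels per axis), and the
dimension is the least-squares slope of log N(ε) against log(1/ε). An
empty set has dimension 0 by convention (unreachable from the
threshold grid, which always retains the maximum voxel).

## Statistical pipeline

Quantile normalization makes every case's feature-value distribution
identical (rank-r value replaced by the across-case mean of rank-r
values; ties interpolate between adjacent reference values). It is
applied to the full table before screening and selection; this leaks
marginal distribution information across cross-validation folds, which
matches how such signatures have historically been built — a strict
per-fold variant exists (`loocv_predictions(..., normalize_per_fold=True)`)
for sensitivity analyses.

Screening is a per-feature two-sided Wilcoxon rank-sum test at
α = 0.05 with no multiplicity correction: exact distribution when both
groups have ≤ 10 cases and no ties, tie-corrected normal approximation
otherwise; an all-constant feature is assigned p = 1. The screen
returns features ordered by ascending p. That ordering is load-bearing:
SFS breaks LOOCV-accuracy ties by screen rank, so when several
candidates achieve equal cross-validated accuracy (common once
accuracy saturates on small cohorts) the tie resolves toward the
stronger marginal association, keeping the procedure deterministic
*and* scientifically sensible.

The classifier is a linear-kernel SVM with C = 1 (both knobs), with
feature standardization re-fit inside every training fold; the
held-out case never influences its own fold's parameters (a leakage
probe in the tests perturbs the held-out case and asserts the fold
parameters are unchanged). The cross-validation unit is the nodule,
not the patient — with multiple nodules per patient this understates
patient-level generalization error. Sensitivity/specificity take
malignant as the positive class.

Baselines: LOOCV on all screened features, and the accuracy
distribution of random k-subsets of the screened set (seeded,
reproducible). Two biases of this design are worth knowing. First,
LOOCV with balanced classes is pessimistic at chance level: the
held-out case's class is always the training minority, so pure-noise
predictors score *below* 50% (observed ≈ 0.38–0.50 on 20/20 null
tables). Second, screened-then-evaluated features carry selection
bias — false positives separate the classes in this sample by
construction — so the random-signature baseline on screened candidates
sits well above chance on small cohorts. Both effects are properties
of the (non-nested) design, not bugs, and both are visible in the
synthetic experiments.

## Synthetic cohorts

Phantoms are ellipsoidal nodules at 1 mm isotropic spacing with a base
intensity of 40 HU and two intensity components: a correlated noise
texture (white noise smoothed with a Gaussian of 1.5 mm correlation
length, rescaled to SD 15 HU) present in both classes, and a coarse
heterogeneity component — 3–6 smooth blobs of random sign at ~1/3
nodule diameter, amplitude 40 HU — present only in the malignant
class. Class separation is therefore purely textural; sizes are drawn
per case from 12–30 mm to emulate cohort diversity (the clinical range
runs to larger nodules; the upper bound keeps per-case extraction
around a second). Per-case seeds are `master_seed + case_index`.

What the phantoms do **not** emulate: lung anatomy (vessels, pleural
attachment), CT physics (beam hardening, reconstruction kernels,
anisotropic slice profiles), partial-solid/GGO composition, or
inter-observer contouring variability. Passing synthetic tests shows
the pipeline is implemented correctly and can recover known texture
signal at realistic noise levels; it does not certify clinical
accuracy on real nodules, for which an independent validation cohort
would be required.

Feature-level experiments use `planted_feature_table`: iid standard
normal features with a +3 SD malignant shift in four named features
(by default the four Laws signature features). The 3 SD effect places
single planted features near perfect separation at n = 20/20 — the
regime in which the recovery experiments probe the *selection*
machinery (screen ordering, tie-breaking, baselines) rather than
borderline detectability, which the screening-calibration and power
tests cover separately.

## Problem sizes

The test suite and the reproduction script run full 750-feature
extraction on nodules of 8–30 mm at 1 mm spacing (≈ 0.3–1.5 s per
case), cohorts of 75 cases for the end-to-end study, 20-seed
replications for the stochastic recovery property, and 200–1000 draws
for the random-signature baseline. These sizes were chosen to make
the complete analysis reproducible on a single CPU in minutes while
keeping every statistical check adequately powered.

## Known limitations

* The 750-name inventory fixes one specific statistic set and filter
  configuration; other radiomics toolkits bin, normalize and name
  features differently, so absolute feature values are not portable
  across toolkits without harmonization.
* Signature evaluation reuses the cohort that selected the signature
  (non-nested SFS/LOOCV); reported accuracies are optimistic relative
  to an external validation set.
* No ROC/probability calibration — the SVM is evaluated purely on
  hard-label accuracy, sensitivity and specificity.
* DICOM series assembly and RT-STRUCT contour conversion are out of
  scope; masks are an input.
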