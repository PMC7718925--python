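# Methods

## Overview

`hessrad` turns a 3D CT volume and a co-registered binary tumor mask (GTV)
into a prognostic model in five stages: isotropic resampling, Hessian-index
image generation, radiomic feature extraction, elastic-net Cox candidate
selection with stepwise signature construction, and rad-score risk
stratification evaluated by Kaplan–Meier curves and the log-rank test. This
note records the model assumptions, the numerical choices made where the
design was genuinely open, and the limits of what the synthetic-data tests
demonstrate.

## Geometry and resampling

Volumes are scalar arrays with voxel spacing in mm and a world origin;
world coordinates are `origin + index * spacing` with 0-based indices.
Masks must arrive voxelized on the same grid — no registration or contour
parsing is attempted.

`resample_isotropic` brings anisotropic acquisitions to an isotropic grid
(default isovoxel 0.98 mm). Intensities use cubic spline interpolation; the
mask goes through shape-based interpolation: its signed Euclidean distance
transform (positive inside, computed in mm so anisotropic spacing is
honored) is interpolated linearly and re-thresholded at zero. This keeps
the result strictly binary with smooth boundaries, unlike nearest-neighbor
resampling which staircases, or linear interpolation of the binary values
which requires an arbitrary threshold. No anti-aliasing prefilter is
applied on downsampled axes.

## Hessian index images

At each voxel the Hessian of the Gaussian-smoothed intensity is computed by
convolving the image with the analytic second partial derivatives of a 3D
Gaussian (derivative-of-kernel form), separably per axis. Three scales are
used — σ = 0.5, 1.0, 1.5 mm paired with kernel sizes 3, 5, 7 voxels — so the
filter bank probes heterogeneity around the 1 mm isovoxel scale. σ is
interpreted in mm and divided by the voxel spacing for sampling; derivative
outputs are per mm².

**Kernel moment normalization.** The sampled, truncated Gaussian-derivative
taps are corrected to satisfy the discrete moment conditions of the
operators they approximate: smoothing taps sum to 1; first-derivative taps
satisfy Σ t·w = 1 (correlation convention); second-derivative taps satisfy
Σ w = 0 and Σ t²·w = 2. Without this correction the truncation is severe at
these kernel sizes (at σ = 0.5, k = 3 the raw second-derivative taps sum to
≈ −0.59, not 0), which leaks a multiple of the local intensity into the
second derivative and can flip eigenvalue signs on smooth quadratic
patches. With the correction, filtering any quadratic polynomial is exact,
so the index of the archetype fields ±(x²+y²+z²), x²+y²−z², x²−y²−z² is
exactly 3/0/1/2 at interior voxels at every scale — the property the tests
assert. At σ = 0.5, k = 3 the corrected taps reduce to the classical central
differences; at larger kernels they retain their Gaussian weighting.

**Eigen-count.** Eigenvalues of the symmetric 3×3 Hessian are obtained with
a standard symmetric eigensolver (`numpy.linalg.eigvalsh`, batched over all
voxels); tests cross-check a closed-form characteristic-polynomial oracle.
Only the signs matter for the index. An eigenvalue counts as negative when
it lies below `−ε` with `ε = 1e−8 · max(1, max|H|)` over the volume, so
exactly flat regions deterministically get index 0 rather than depending on
floating-point noise around zero. ε is configurable.

**Averaging and requantization.** Each raw index image (values 0–3) is
box-averaged with 3³ and 5³ kernels and the continuous mean m ∈ [0, 3] is
mapped to `round(m/3 · 255)` — the minimal full-range linear 2-to-8-bit
mapping. Rounding throughout the package is half-away-from-zero. Borders
use replicate (nearest) padding for both derivative and averaging
convolutions; border-adjacent voxels are used as-is downstream since GTVs
are interior in practice. The index is computed over the full volume and
masked only at feature extraction, because the averaging filters need
spatial context beyond the GTV boundary. The result is six index images
per CT, ordered by σ then averaging kernel.

## Feature extraction

**Histogram set (14).** mean, variance, skewness, kurtosis (Pearson),
median, min, max, range, energy, entropy, uniformity, RMS, mean absolute
deviation, and the 10th–90th interpercentile span, computed on raw in-mask
values (HU for CT, 8-bit values for index images, raw coefficients for
wavelet sub-bands). Entropy and uniformity need a discrete distribution:
continuous inputs are binned into a fixed 64-bin histogram over the ROI's
min–max range; a constant ROI has entropy 0 and uniformity 1, and skewness/
kurtosis of a zero-variance ROI are defined as 0.

**Texture set (40).** Four matrices over quantized gray levels with 3D
26-connectivity, out-of-mask voxels fully excluded:

* GLCM — voxel pairs at distance 1 along the 13 unique directions,
  aggregated into one matrix, symmetrized, normalized to sum 1; 9 features
  (energy, contrast, correlation, homogeneity, variance, sum average,
  entropy, dissimilarity, autocorrelation).
* GLRLM — maximal equal-level runs along the same 13 directions pooled into
  one matrix; 13 features (SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE,
  SRHGE, LRLGE, LRHGE, GLV, RLV).
* GLSZM — 26-connected iso-intensity zones; the analogous 13 features.
* NGTDM — absolute difference from the mean of in-mask 26-neighbors,
  accumulated per level; 5 features (coarseness, contrast, busyness,
  complexity, strength; coarseness of a perfectly flat ROI is capped at the
  valid-voxel count instead of dividing by zero, and pairwise statistics
  are 0 when fewer than two levels are present).

Gray levels enter the statistics as 1-based bin indices over the full
quantization range. The feature lists live in a single registry with frozen
ordering so tables are reproducible across runs; the partition 9/13/13/5
follows common radiomics-toolbox convention and is swappable.

CT texture uses the fixed 8-bit look-up table mapping −1000…1500 HU to
0…255 with clamping (`level = round((v + 1000)/2500 · 255)`); index images
are already 8-bit and feed the matrices directly. The level count (256) is
configurable since sparse matrices at 256 levels are a known practical
concern for very small ROIs.

**Wavelet set (432).** One level of an undecimated (stationary) separable
3D decomposition with the orthonormal coiflet-1 filters, whole-sample
symmetric extension, producing the 8 sub-bands LLL…HHH at the original grid
size so every sub-band stays aligned with the mask; the undecimated form
avoids the mask down-sampling a decimated transform would force, and makes
the features invariant to whole-voxel translations. Low-pass taps keep
their orthonormal normalization (they sum to √2 per axis). Each sub-band
contributes the 54 histogram + texture features: histogram statistics on
raw coefficients, texture statistics after per-sub-band min–max
requantization to 256 levels (sub-band values have no fixed physical
scale; a constant sub-band maps to level 0). Totals: 486 conventional
(14 + 40 + 8×54) and 324 index (6×54) features, 810 disjoint names.
Index images get no wavelet features — the directional filters would
reintroduce the rotational dependence the index was constructed to avoid.

## Signature construction

**Candidate selection.** Elastic-net-penalized Cox regression with blending
parameter α (1 = lasso, →0 = ridge) over the grid
{0.01, 0.02, 0.05, 0.08, 0.1, 0.2, 0.5, 0.8, 1.0}. Features are z-scored
with training-cohort statistics before fitting. For each α a 50-point
penalty path is fitted on the full training set and scored by 5-fold
cross-validation, the criterion being the held-out fold's Cox partial
log-likelihood (Breslow ties) evaluated at the training-fold coefficients;
the α whose path maximum is largest wins, and candidates are the features
with non-zero coefficients at the maximizing penalty. An empty selection is
a valid outcome. A combined candidate set pools the conventional and index
candidates and re-runs the selection. Folds are seeded, so selection is
deterministic.

**Combination strategy.** Nested greedy forward selection: starting from
the empty set, at each step every remaining candidate is tentatively added,
an unpenalized Cox model (Efron ties) refit, and the training-cohort
median-rad-score-split log-rank p-value computed; the candidate with the
lowest p is appended. Ties break toward the higher concordance index, then
the lexicographically smaller name. Candidates whose refit fails
(collinearity, separation) are skipped. This yields signatures of sizes
1…K with K ≤ min(12, n/10) — at most one feature per ten training patients
— each storing its coefficients (original feature scale) and training
rad-score median. Nesting was chosen over an independent re-search per size
for determinism and interpretability; the strategy is a single function and
can be swapped for a bootstrap-based variant.

**Clinical variables.** Stages are encoded ordinally (T1–T4 → 1–4, N0–N3 →
0–3, overall stage I–IVB → 1–6, sub-stages collapsed to their parent tier
for T/N), HPV status as 1/0, age and tumor volume numerically; missing
values propagate as NaN and are excluded per analysis. Clinical signatures
are built by the same combination strategy, and integrated signatures are
the Cartesian product of radiomic × clinical signatures, each refit as one
joint Cox model (12 × 5 = 60 when both lists are full).

## Evaluation

The rad-score is the coefficient-weighted sum of signature features, no
intercept. Patients with scores strictly above the training median are
high-risk; ties go to the low-risk group. Kaplan–Meier curves are estimated
per group and compared with the two-sample log-rank test (statistic
referred to χ²(1), two-sided, no continuity correction). Degenerate cases
— an empty group, or an all-censored cohort — report the p-value as
missing with a warning rather than raising. Model selection over the
signature sizes picks the lowest test-cohort p (ties toward the smaller
signature). The streak-artifact analysis applies the same stratification
separately to artifact-flagged and unflagged subgroups and reports both
p-values and their absolute difference; survival-time units are carried
through opaquely.

## Synthetic data

Phantoms place analytic primitives on a uniform background: Gaussian blobs
(bright/dark, width given as FWHM in mm to align with the filter scales)
and quadratic saddle patches written inside a spherical top-hat window
(default radius 8 mm) wide enough that the window edge cannot influence the
center through any kernel. The GTV mask is an ellipsoid covering the
primitive supports plus a margin. Ground truth is the analytic index at
each primitive center. Noise is additive Gaussian in HU.

Cohorts draw features (standard normal by default), survival times from
`h(t|x) = rate · exp(βᵀx)` with an exponential baseline, and independent
exponential censoring whose rate is solved (bisection on
`mean_i c/(c + r_i) = target`) so the expected censoring fraction matches
the target; at n ≥ 200 the achieved fraction lands within a few percentage
points. Both generators are bit-reproducible given their seeds.

What these generators deliberately do **not** emulate: streak artifacts,
Poisson/quantum noise, scanner and reconstruction-kernel variability,
contrast enhancement, anatomically realistic tumor shapes, or correlation
structure between image-derived features and survival beyond the
proportional-hazards law. Passing tests therefore demonstrate algorithmic
correctness (exact index semantics, matrix definitions, estimator
behavior), not clinical performance on real cohorts.

## Problem sizes and tolerances

The test suite and acceptance script use a 64³ noisy phantom for the
structural checks, 24³ grids for the analytic index properties, ≤5³ ROIs
with ≤4 levels for exhaustive texture-matrix enumeration, and simulated
cohorts of n = 120–500 with 10–100 replicates for the statistical checks —
sizes at which every property is decisive while the full run stays fast on
a single CPU. Exact properties (index values on quadratics, rotation
invariance, texture-matrix equality) are asserted with zero tolerance;
statistical recoveries use the conventional 3-standard-error band, and
log-rank power at hazard ratio 3 with 200 patients per arm is required in
at least 95% of replicates at p < 0.001.

## Known limitations

* GLSZM construction loops over the gray levels present in the ROI (one
  connected-component labeling each); at 256 levels on large ROIs this is
  the slowest extraction step, though still seconds per image.
* The Coxnet cross-validation scores the held-out fold's own partial
  likelihood, which is noisy for very small folds; the spec-level behavior
  (sparser selections at α = 1 than near ridge, informative features
  retained) is what the tests pin down.
* DICOM reading supports axial CT series with consistent orientation and
  spacing; RTSTRUCT contours are out of scope by design.
* Feature values near the volume border inherit replicate-padding effects;
  GTVs are assumed interior.
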