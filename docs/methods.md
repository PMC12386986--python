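# Methods

## Scope and analysis unit

All analysis is 2D and per slice: one grayscale raster plus one binary
lesion mask is the unit from which features are computed. Volumetric
variants, PET-driven localization, scanner physics and motion correction
are out of scope; masks (or rectangular seed regions for the segmenter)
are inputs.

## Preprocessing

Intensities are z-score normalized over the whole image (mean 0, sd 1)
before feature extraction. The first-order medians on z-scored images
are naturally zero-centered with unit-order dispersion, which is the
scale on which the feature conventions below were chosen. Normalization
is idempotent, affine-invariant and rank-preserving; a constant image is
a hard error.

Segmentation runs Otsu's threshold on a 256-bin histogram of the
intensities inside a rectangular seed region, takes the brighter class
as lesion (a polarity flag inverts this for dark-lesion contrast),
applies a configurable morphology sequence (default `open`, `close`,
disk radius 1) and keeps the largest 8-connected component. Segmentation
operates on raw intensities and normalization follows; since Otsu on a
fixed-bin histogram is invariant to affine intensity maps, the order
only matters for pathological inputs, and it is a config switch.

## Discretization and the classical families

Foreground intensities are binned into G = 32 equal-width levels over
the foreground range (min → 1, max → G). A fixed bin count rather than a
fixed bin width is used because the z-scored intensity scale has no
absolute units. The matrix families follow the IBSI-consistent
definitions:

- GLCM: symmetric co-occurrence at distance 1; the 22 features are
  computed per 2D direction ((0,1), (1,0), (1,1), (1,−1)) and averaged
  over directions that contain at least one in-mask pair.
- GLDM: dependence = 1 + number of 8-neighbors (in mask) whose level
  matches the center within α = 0.
- GLRLM: runs per direction, broken by off-mask pixels; per-direction
  feature values averaged.
- GLSZM: zones are 8-connected equal-level components.
- NGTDM: per-level sums of |level − mean(8-neighbor levels in mask)|
  over pixels with at least one in-mask neighbor.

Degenerate conventions are the widely used ones: Correlation of a
constant ROI is 1, IMC1/IMC2 fall back to 0, Inverse Variance sums only
off-diagonal cells, NGTDM Coarseness is capped at 1e6 when the
gray-tone difference sum is zero. Kurtosis is unadjusted (normal → 3);
Skewness is the Fisher–Pearson moment coefficient; robust MAD is the
mean absolute deviation of the values inside [P10, P90]. Feature names
are family-prefixed (`GLCM_Contrast`, `GLRLM_GLN`) because several short
names recur across families.

## Fractal features

`ID(k)` is the mean absolute intensity difference over all horizontal
and vertical pixel pairs at offset k with both members in the mask,
divided by the exact number of such pairs (which also handles irregular
masks; a closed-form denominator valid only for full square masks is
not used). The Hurst exponent is the OLS slope of log ID(k) on log k
over scales k = 1..s (default s = min(8, side/4)); zero-valued scales
and scales with fewer than 16 valid pairs are excluded, and fewer than
two usable scales is an error. The estimator is not clamped: the fit
carries an out-of-range flag when H leaves [0, 1], and only the FD
conversion (FD = 3 − H at the finest resolution) clamps H into [0, 1]
so FD stays in [2, 3].

The multiresolution vector applies m = 3 successive 2×2 mean-pooling
steps (mask pooled by majority, ties → foreground) and re-estimates H at
each level; FSVI is the least-squares slope of H_i against the level
index i = 0..m−1. Because the pooling grid is fixed, FSVI is invariant
to translations by multiples of 2^(m−1) pixels but can shift slightly
under odd offsets — the same behavior as any decimating multiscale
transform.

Lacunarity glides a box (stride 1) over the mask bounding box; box mass
is the count of "occupied" pixels, where the default occupancy rule is
*in mask and intensity above the image mean* (on z-scored images this is
binarization at zero). Λ(b) = var/mean² of the mass; the reported
scalar is the mean of Λ over box sizes {2, 4, 8}, clipped to boxes that
fit the bounding box. The occupancy rule and box sizes are
config-exposed since a single reported scalar does not pin them down.

## Synthetic cohorts

`generate_fbm_surface` synthesizes fBm spectrally: white complex
Gaussian noise shaped by the amplitude |f|^−(H+1), inverse FFT, real
part, standardized. Two corrections make lattice increments track the
continuum law: the field is generated on a 2× larger domain and cropped
(FFT periodicity), and on a 4× finer grid and decimated (band-limited
FFT fields otherwise lack sub-pixel detail, biasing small-lag increment
scaling upward for rough surfaces). With both corrections the mean
Hurst-recovery error on 256×256 surfaces stays within ±0.07 across
H ∈ {0.2, 0.5, 0.8}; this was calibrated by simulation and is re-measured
by the acceptance script.

A cohort sample is an fBm surface with an elliptical, boundary-jittered
lesion mask: lesion texture scaled by the class `intensity_sd`
(background at unit scale), a constant brightness plateau added inside
the mask (tapering only outside it, so within-mask texture is shifted,
never re-shaped), clustered disk-shaped "gap" patches overwritten with a
low intensity (the whole-image 25th percentile — clearly below the
occupancy threshold yet shallow enough not to dominate increment
scaling) covering the class `gap_fraction` of the lesion, and a small
per-patient intensity offset so images of one synthetic patient
correlate.

Class defaults (calibrated by simulation, directions asserted, values
not): ADC-like H = 0.60, sd = 1.25, gaps = 0.10; SCC-like H = 0.53,
sd = 1.00, gaps = 0.02. These place the extracted FD medians at roughly
2.36 (ADC) vs 2.47 (SCC) and reproduce the contrast directions reported
for clinical cohorts — ADC lower FD, higher lacunarity, higher
dispersion. What
the generator does *not* emulate: scanner noise spectra, partial-volume
and motion effects, anatomical background structure, inter-scanner
variation, or 3D continuity between slices. Passing tests therefore
demonstrate correctness and calibration of the estimators and the
direction logic of the pipeline, not clinical performance on real MR
data.

## Selection, classification, evaluation

Feature importances come from a 200-tree random forest with fixed seed
42 (reproducibility convention); importances sum to 1 and the top
k ≤ 40 features are kept, ties broken lexicographically. An
importance ≥ mean cutoff is available as an alternative. kNN uses k = 7
Euclidean neighbors on features z-scored with train-set statistics; the
score is the positive-neighbor fraction, so with odd k votes never tie.
Point metrics come from a stratified 75/25 holdout; CV accuracy from
stratified 5-fold cross-validation — both reported because a single
point metric on its own does not identify the protocol. With
`grouping="patient"` both the holdout (stratified at patient level) and
the folds (StratifiedGroupKFold) keep a patient's images on one side;
this is the recommended mode, since repeated images per patient
otherwise leak identity into image-level splits (measurably: null
cohorts score above 0.5 AUC with image-level splits and ~0.5 with
patient grouping).

## Group statistics

Per feature: Shapiro–Wilk per group at α = 0.05 routes to Welch's
unequal-variance t-test (both normal) or two-sided Mann–Whitney U
(otherwise; exact enumeration when both groups have n ≤ 8, normal
approximation with tie correction above). Constant groups route to
Mann–Whitney with a warning. Quartiles use linear interpolation between
order statistics. No multiple-testing correction is applied by default,
matching common per-feature reporting; `benjamini_hochberg` is provided,
and with 93 features about 5% false positives are expected under the
null without it. A per-patient-mean mode avoids treating repeated
images of one patient as independent.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeds; a
  pipeline run fans one global seed out to stages by fixed offsets, and
  fixed seed ⇒ byte-identical outputs.
- Problem sizes in the test and acceptance runs (64×64 cohort images,
  10 + 10 patients × 5 images, 20 replicate cohorts, 50 fBm seeds at
  256×256) were chosen as the smallest sizes at which the Monte-Carlo
  checks are stable across seeds.
- The multiresolution level count defaults to m = 3, requiring at least
  32 pixels per side so the coarsest level keeps 8; requesting more
  levels than the image supports reports the feasible maximum.
- Known limitations: the Hurst estimator retains a small positive bias
  for very rough textures (H ≈ 0.2) inherited from lattice effects;
  FSVI is sensitive to pooling-grid alignment (above); lacunarity
  depends on the occupancy rule, so comparisons are only meaningful at
  fixed extraction settings.
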