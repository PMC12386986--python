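# fractalrad

Fractal-radiomics texture analysis for differentiating lung-tumor
subtypes on 2D MR slices.

Non-small cell lung cancer (NSCLC) splits into two major subtypes —
adenocarcinoma (ADC) and squamous cell carcinoma (SCC) — that call for
different treatment but are hard to tell apart by visual reading of MR
images. `fractalrad` implements a quantitative pipeline for this
problem: lesion segmentation, extraction of 93 texture features per
region of interest, random-forest feature selection, k-nearest-neighbors
classification, and per-feature group statistics. Its distinguishing
component is the fractal feature family, which models tumor texture as a
fractional Brownian motion (fBm) surface.

## The model

For an fBm surface the expected absolute intensity difference between
pixels a distance *k* apart scales as a power law,

```
E|ΔI| ∝ k^H,          H ∈ (0, 1),
```

with Hurst exponent *H*. The package estimates *H* as the ordinary
least-squares slope of `log ID(k)` against `log k`, where `ID(k)` is the
mean absolute intensity difference over all horizontal and vertical
in-mask pixel pairs at distance *k* (the multiscale intensity difference
vector `[ID(1) … ID(s)]`). Three scalar features summarize the fractal
structure of an ROI:

- **FD = 3 − H** — fractal dimension; large FD = rough, space-filling
  texture, small FD = smooth.
- **FSVI** — the least-squares slope of the Hurst exponents computed at
  successively 2×-downsampled resolutions against the level index;
  zero for an exactly self-similar surface, nonzero when roughness is
  scale-dependent.
- **Lacunarity Λ = var(M)/mean(M)²** of the occupied-pixel mass *M* of
  boxes gliding (stride 1) over the mask bounding box, averaged over box
  sizes {2, 4, 8}; measures "gappiness" at fixed roughness.

Around this core, the classical families follow the standard
(IBSI-consistent) definitions: 17 first-order statistics and 73 features
from the gray-level co-occurrence (22), dependence (14), run-length
(16), size-zone (16) and neighboring gray-tone difference (5) matrices —
93 features in total. Selection uses impurity-based importances from a
200-tree random forest (seed 42); classification uses k = 7 nearest
neighbors on z-scored features, scored by holdout metrics
(accuracy/precision/recall/F1/ROC-AUC, positive class = SCC) and
stratified 5-fold cross-validated accuracy. Group comparisons report
median (Q1; Q3) per class with Welch's t-test when both groups pass
Shapiro–Wilk normality and the Mann–Whitney U test otherwise.

Because the real cohort is an external download, the package ships a
first-class synthetic-data module: two-class cohorts of fBm lesion
textures with known Hurst exponent, gap structure and intensity
dispersion, oriented the same way as the contrasts reported for
clinical ADC/SCC cohorts (ADC-like: lower FD, higher lacunarity, higher
variance).

## Worked example

```sh
python examples/classify_subtypes.py
```

```
cohort: 64 images, 93 features
FOS/SOS/FDTA   accuracy=1.00 precision=1.00 recall=1.00 f1=1.00 auc=1.00 cv_accuracy=1.00
FOS/SOS only   accuracy=1.00 precision=1.00 recall=1.00 f1=1.00 auc=1.00 cv_accuracy=1.00
top 5 features: GLRLM_RV, GLDM_DV, GLCM_MP, FOS_10th Percentile, GLDM_LDE
```

The synthetic classes are well separated at the default contrasts, so
both feature sets classify this small cohort perfectly; on noisier
cohorts the fractal features add measurable AUC (see the acceptance
outputs below). And the fractal features themselves:

```sh
python examples/fractal_features.py
```

```
true H = 0.6, estimated H = 0.620 (r^2 = 1.0000)
H by resolution level: [0.62  0.685 0.657]
FD = 2.380  (3 - H; larger = rougher)
FSVI = +0.019  (scale drift of H; ~0 for self-similar fBm)
Lacunarity = 0.478  (gappiness; 0 = uniformly occupied)
```

The estimated Hurst exponent recovers the generating value to ±0.02
here; FD is its mirror; FSVI is near zero because pure fBm is
self-similar across resolutions.

Other examples: `segment_and_extract.py` (Otsu segmentation of a known
ellipse, Dice = 1.000), `group_statistics.py` (median (Q1; Q3) tables
and test routing), `run_pipeline.py` (full seeded run into an output
directory). A thin CLI mirrors the stages:

```sh
fractalrad simulate --patients-per-class 5 --images-per-patient 3 --seed 1 --out cohort/
fractalrad extract --manifest cohort/manifest.csv --out features.csv
fractalrad classify --features features.csv --grouping patient --out report.json
fractalrad run-all --seed 1 --out run/
```

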