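# noduleomics

Radiomics analysis of 3D CT lung nodules: a 750-feature extractor and
the statistical pipeline that builds and evaluates a small feature
*signature* for benign/malignant classification.

## The problem

Whether a pulmonary nodule seen on CT is benign or malignant is
conventionally settled by invasive biopsy. Radiomics offers a
non-invasive alternative: extract a large battery of quantitative
descriptors from the delineated nodule volume and learn which few of
them discriminate the classes. The discriminative content is largely
*within-nodule heterogeneity* — spot/edge micro-structure that texture
filter banks (Laws kernels in particular) pick up.

`noduleomics` implements that analysis end to end for anyone who has
3D volumes (NIfTI/NRRD) with co-registered binary nodule masks:

1. **Feature extraction** — exactly 750 named features per nodule:

   | category | count |
   |---|---|
   | intensity & shape (16 statistics + 10 IVH + 7 shape) | 33 |
   | Laplacian-of-Gaussian, σ ∈ {1…6} mm × 16 statistics | 96 |
   | 3D wavelet subbands (LLL…HHH) × 16 statistics | 128 |
   | Laws texture kernels (27 L/E/S triples) × 16 statistics | 432 |
   | gray-level co-occurrence (GLCM, 13 directions, 256 levels) | 26 |
   | run-length (RLM, 13 directions, 256 levels) | 11 |
   | size-zone (GLSZM, 26-connected) | 11 |
   | neighborhood gray-tone difference (NGTDM) | 5 |
   | box-counting fractal dimension (8 thresholds) | 8 |

2. **Signature building** — quantile normalization across cases,
   per-feature two-sided Wilcoxon rank-sum screening (p < 0.05,
   uncorrected), then sequential forward selection (SFS): greedily add
   the feature maximizing leave-one-out cross-validated accuracy of a
   linear SVM (C = 1, per-fold standardization) until k = 4 features.

3. **Evaluation** — LOOCV confusion counts (accuracy, sensitivity,
   specificity with malignant as the positive class), plus two
   reference baselines: all screened features at once, and the mean
   accuracy of random k-subsets of the screened set.

A synthetic-cohort module generates two-class ellipsoidal nodule
phantoms whose classes differ only in regional texture heterogeneity,
so the whole pipeline is testable without patient data.

## Worked example

```bash
noduleomics simulate --n-benign 4 --n-malignant 4 --out-dir cohort --seed 7
noduleomics extract  --manifest cohort/manifest.csv --out features.csv
noduleomics analyze  --table features.csv --out-dir results -k 2 --n-perm 50 --seed 7
```

which prints (feature CSV: 8 cases × 750 columns):

```
wrote 8 cases to cohort/manifest.csv
wrote 8 cases x 750 features to features.csv
signature: RLM_RLN, Wav_LLL_max
accuracy 100.0%, sensitivity 100.0%, specificity 100.0%
report written to results/analysis_report.json
```

The signature is the ordered pair of features SFS selected; the three
percentages are LOOCV metrics of that signature on the 8 phantoms
(tiny, well-separated cohorts are typically classified perfectly —
see `docs/methods.md` for what synthetic performance does and does not
mean). `results/analysis_report.json` additionally holds the screened
features with p-values, the confusion counts, both baselines, and the
full configuration echo.

The same three stages are available as library calls
(`noduleomics.generate_cohort`, `extract_cohort`, `quantile_normalize`,
`wilcoxon_screen`, `sfs_select`, `loocv_evaluate`, …) for use on real
cohorts, which enter at the `extract` stage (a manifest CSV naming
image/mask pairs) or the `analyze` stage (a feature-table CSV).

## Layout

```
src/noduleomics/
  volumes.py     volume/mask I/O, ROI cropping, gray-level quantization
  synthetic.py   nodule phantoms, cohort writer, micro-fixtures
  intensity.py   16-statistic summary, IVH, shape features
  filters.py     Laws / wavelet / LoG banks
  matrices.py    GLCM, RLM, GLSZM, NGTDM, fractal dimension
  extract.py     750-feature assembly, cohort extraction
  registry.py    the canonical feature-name registry
  pipeline.py    normalization, screening, SFS/SVM/LOOCV, baselines
  cli.py         simulate / extract / analyze / registry subcommands
docs/methods.md  models, conventions, parameter choices, limitations
```
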