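# lodgetex

Plot-level classification of soybean lodging severity from UAV-style
orthomosaic imagery.

Breeding programs score lodging — stems bending or breaking until plants
lean or lie flat — visually on a 1–5 scale per plot, then group the scores
into four classes: no lodging (NL), moderate (ML), high (HL) and severe
(SL).  In a real breeding trial these classes are badly imbalanced
(roughly 964 : 206 : 85 : 11 over 1266 plots), which cripples naive
classifiers.  `lodgetex` implements the full image-to-report pipeline for
this problem and is aimed at plant-phenotyping researchers and
agricultural data scientists who want a tested, reproducible reference
implementation:

* a **synthetic field generator** (no field dataset is distributable)
  producing orthomosaic-like images whose canopy texture heterogeneity
  grows with lodging severity;
* **canopy segmentation** via Chan–Vese active contours with small-region
  cleanup;
* **GLCM texture features** — the 14 classical Haralick statistics
  (angular second moment, contrast, correlation, …, maximal correlation
  coefficient) computed over the canopy mask from direction-averaged
  co-occurrence matrices;
* **RF-RFE feature selection** (random-forest recursive feature
  elimination with 10-fold cross-validated scoring);
* five **native imbalance treatments** — SMOTE-Tomek, SMOTE-ENN,
  Borderline-SMOTE, SMOTE-NC, ADASYN — applied to the training split only;
* four **classifiers** (XGBoost with a TPE tuner, grid-searched random
  forest, native k=3 KNN, single-hidden-layer ANN) behind one
  fit/predict/predict_proba contract;
* a full **evaluation suite**: confusion matrix, overall accuracy
  OA = trace/N, Cohen's kappa κ = (P₀ − Pₑ)/(1 − Pₑ), one-vs-rest
  precision/recall/F1, ROC-AUC and average precision per class.

The published held-out confusion matrices for the four classifiers on the
SMOTE-ENN-balanced dataset ship as in-repo fixtures and serve as the
package's primary regression surface.

## Worked example

Recompute every published held-out metric from the bundled matrices
(`python examples/05_fixture_metrics.py`):

```
xgboost  n=527  OA 0.94  kappa 0.91  SL precision/recall/F1 0.99/0.99/0.99
rf       n=527  OA 0.93  kappa 0.91  SL precision/recall/F1 0.98/0.99/0.98
knn      n=527  OA 0.91  kappa 0.88  SL precision/recall/F1 0.97/1.00/0.99
ann      n=527  OA 0.96  kappa 0.94  SL precision/recall/F1 1.00/0.99/1.00
```

Each line is one classifier evaluated on 527 held-out plots after
SMOTE-ENN balancing: OA is the fraction classified correctly, kappa the
chance-corrected agreement, and the SL columns show that severe lodging —
the class with only 11 original training plots — is recovered almost
perfectly once the training data are balanced.

Or run the whole synthetic pipeline from images to reports:

```python
from lodgetex import RunConfig, run_pipeline

run_dir = run_pipeline(RunConfig(seed=7, out_dir="runs/demo"))
# run_dir now contains field.png, plots.csv, features.csv,
# one report_<resampler>_<model>.json per pair, and a checksummed manifest
```

The other `examples/` scripts each demonstrate one capability: field
simulation, segmentation + texture features, the five resampling plans,
and training/evaluation on imbalanced tabular data.  A thin CLI mirrors
the library (`lodgetex run-all`, `lodgetex simulate`,
`lodgetex fixture-eval ann`).

## Layout

```
src/lodgetex/      synth, segment, texture, selection, resample,
                   models, metrics, pipeline, cli
src/lodgetex/data/ published held-out confusion matrices (CSV)
examples/          one short narrative script per capability
docs/methods.md    model, conventions, parameter choices, limitations
tests/             unit, property and acceptance suites
```
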