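# Methods

## Problem and scope

Breeding programs score soybean lodging visually on a 1–5 scale (0.5
increments) per four-row plot; the scores group into four classes —
no lodging (NL: 1.0, 1.5), moderate (ML: 2.0, 2.5), high (HL: 3.0, 3.5) and
severe (SL: 4.0, 4.5, 5.0).  This package implements a plot-level
classification pipeline for UAV-style orthomosaic imagery: canopy
segmentation, gray-level co-occurrence (GLCM) texture features, feature
selection, imbalance-aware resampling, four classifiers and a full
multiclass evaluation suite.  Because no field imagery dataset is
distributable, the package ships a synthetic field generator with the same
statistical structure (a 964/206/85/11 class imbalance over 1266 plots) and
uses the published held-out confusion matrices as its regression surface.

## Synthetic field generator

Each plot patch is rendered as a canopy base intensity (170 on the 8-bit
scale) plus three additive components per class:

* fine Gaussian grain (sd 4 → 16 from NL to SL) — canopy micro-texture;
* an oriented sinusoidal streak field (amplitude 0 → 25, period 8 px,
  random orientation/phase per plot) — the directional pattern of flattened
  stems;
* exposed-soil blotches (expected area fraction 0 → 0.32), cut from
  smoothed thresholded noise and filled at the soil intensity (70) — gaps
  opened where plants fall.

Patches are placed on a near-square grid over a soil-textured background
(level 70, grain sd 6); the layout emulates a breeding trial of four-row
plots without radiometric or geometric stitching artifacts.  Class labels
are shuffled across grid positions and every generator consumes one
explicit integer seed, so identical configs are bit-identical.

The generator's contract is qualitative, not radiometric: expected GLCM
contrast increases strictly NL→SL (whole patch and canopy-masked), the
canopy-masked angular second moment decreases strictly, and the segmented
foreground fraction drops as soil gaps open.  Whole-patch ASM is *not*
monotone at the severe end — uniform exposed soil concentrates
co-occurrence mass — which is exactly why texture features are computed
over the canopy mask in the pipeline.  Parameter values were chosen once
so that canopy intensities (minimum ≈ 115 for SL) stay well above soil,
keeping the two-phase segmentation anchored on the canopy/soil boundary
rather than on lodging streaks.

What the generator does not emulate: perspective and stitching artifacts,
illumination gradients, shadows, plot-size variation, weeds, and the
spectral detail of real canopies.  Passing the end-to-end tests therefore
demonstrates the pipeline's internal correctness and its behaviour under
the study's imbalance regime, not field-data accuracy.

### Small-scale run conditions

Quick end-to-end runs use class counts {NL: 90, ML: 22, HL: 12, SL: 6}
(n = 130).  Scaling the original ratio to 130 plots would leave a single
severe-lodging plot, which can neither be stratified-split nor
k-NN-oversampled; the chosen counts preserve a strong imbalance
(69/17/9/5 %) while every class survives an 80/20 split with at least two
training members.

## Segmentation

Plot ROIs are cropped with 0-based half-open rectangles.  Canopy is
separated from soil by minimizing the piecewise-constant (Chan–Vese)
active-contour energy on the grayscale ROI (smoothing weight mu = 0.1,
iteration cap 200, tolerance 1e-4), initialized from a centred rectangle
covering 60 % of the ROI.  The brighter phase is taken as canopy
(configurable polarity), then 8-connected components with area < 25 px are
removed.  The method itself fixes none of these constants; they are
package defaults exposed in `SegmentParams`.  Degenerate inputs (constant
ROI, collapsed segmentation) yield an empty mask plus a warning, never an
exception.

## Texture features

Images are quantized to Ng equal-width gray levels (default 16);
co-occurrences of quantized levels are counted for ordered pixel pairs at
distance d = 1 along 0°, 45°, 90° and 135°, restricted to pairs whose two
pixels both lie inside the canopy mask, symmetrized by adding the
transposed counts and normalized to sum 1.  The four directional matrices
are averaged (rotation robustness) and the 14 classical Haralick
statistics are computed from the average: angular second moment, contrast,
correlation, variance, inverse difference moment, sum average, sum
variance, sum entropy, entropy, difference variance, difference entropy,
two information measures of correlation, and the maximal correlation
coefficient.

Numerical conventions, stated because the classical definitions are
1-based and occasionally ambiguous:

* gray levels are 0-based; the sum distribution p_{x+y} runs over
  k = 0…2Ng−2 and the absolute-difference distribution p_{x−y} over
  k = 0…Ng−1;
* logarithms are base 2 with 0·log 0 := 0;
* "variance" centres on the grand mean level μ = Σᵢ i·pₓ(i);
* sum variance centres on f₈ = sum entropy (the classical definition);
  sum entropy carries the conventional negative sign;
* difference variance is the literal statistical variance of p_{x−y};
* correlation on a constant image (σₓσᵧ = 0) is reported as 0 with a
  degeneracy flag;
* the maximal-correlation Q matrix is restricted to levels with nonzero
  marginals; its second-largest eigenvalue is clipped to [0, 1] before the
  square root, and fewer than two usable levels yield 0 with a flag.

One GLCM is built per whole plot over the masked foreground (not a sliding
kernel): the analysis needs one feature vector per plot.  A plot with an
empty mask (no valid pixel pairs) is skipped and logged rather than
imputed.

## Feature selection

Recursive feature elimination ranked by random-forest Gini importance:
at each step the current set is scored by stratified 10-fold
cross-validated accuracy, a forest (500 trees by default) is refit on all
rows, and the least-important feature is dropped (one per step; importance
ties break to the lower column index).

The selected subset follows the one-standard-error rule: the smallest
feature count whose mean CV score lies within one standard error (of the
best size's fold scores) of the curve maximum.  The strict arg-max is
available via ``tolerance=0`` but is not the default because near its top
the CV curve is flat to within fold-to-fold scatter — a few uninformative
features change the forest's accuracy by less than the score noise — so
the literal maximum effectively samples that noise and frequently retains
features the elimination ranking has already identified as uninformative.
The one-SE rule is the standard remedy for model selection on noisy CV
curves.  Stratified folds and accuracy scoring are package choices where
the protocol is underspecified; `best_score` always reports the curve
maximum.

## Imbalance treatments

All five treatments are implemented natively on the feature table, with
synthetic rows flagged `synthetic`:

* **SMOTE** — each synthetic row is x + λ(y − x), λ ~ U[0,1], with x a
  random minority row and y one of its k = 5 nearest minority neighbours.
* **SMOTE-Tomek** — SMOTE to equalize every class to the majority count,
  then remove majority members of Tomek links (mutual nearest neighbours
  of opposite class).
* **SMOTE-ENN** — SMOTE to equalize, then remove every sample (any class)
  whose label disagrees with the unanimous-majority vote of its k = 3
  nearest neighbours; vote ties keep the sample.  Output counts are
  intentionally unequal and the original majority typically shrinks most.
* **Borderline-SMOTE (variant 1)** — synthesis restricted to "danger"
  minority seeds with at least half, but not all, of their k whole-data
  neighbours in other classes; falls back to all class rows if a class has
  fewer than two danger seeds.
* **ADASYN** — per-minority-point budgets proportional to the fraction of
  other-class points among its k neighbours, totals set to approximately
  equalize (rounding leaves counts within ±2 %).
* **SMOTE-NC** — nominal-aware SMOTE: nominal mismatches add the squared
  median of the continuous features' standard deviations to the squared
  distance, and synthetic nominal values take the neighbourhood mode.
  With zero nominal columns the code path is plain SMOTE equalization,
  draw for draw.

Distance ties everywhere break toward the lowest row index (stable sort),
which makes every plan bit-reproducible under a fixed seed.  Resampling is
applied to the training split only; the held-out split always consists of
original rows (asserted via provenance flags).

## Classifiers and tuning

All four models sit behind one `fit`/`predict`/`predict_proba` contract
with probability rows summing to 1 in a fixed NL, ML, HL, SL class order.

* **XGBoost** — gradient-boosted trees, tuned by a compact sequential
  Tree-structured Parzen Estimator written in this package: after a random
  start-up, observed trials are split at the γ = 0.25 quantile into good
  and bad sets, each search dimension gets 1-D Gaussian Parzen mixtures
  over both sets, and of 24 candidates drawn from the good-set mixture the
  one maximizing Σ(log l − log g) is evaluated next.  The space covers
  n_estimators, learning rate (log), max depth, subsample, colsample and
  min child weight; the objective is mean stratified 5-fold CV accuracy.
* **Random forest** — grid search over six parameters (trees, max depth,
  max features, min samples split, min samples leaf, bootstrap) with
  5-fold CV; a budget below the grid size evaluates a seeded random subset.
* **KNN** — fixed k = 3, no search, implemented natively: brute-force
  Euclidean distances, vote-fraction probabilities, distance ties to the
  lowest training index.
* **ANN** — single hidden ReLU layer with softmax output, tuned over
  hidden width {16, 32, 64, 128} and iteration cap {200, 400}; early
  stopping off.

Features are standardized with training-set mean/sd for KNN and the ANN
only; tree ensembles consume raw features.  Degenerate one-class training
data yields a constant predictor.  All backends run single-threaded with
explicit seeds, so fits are deterministic.

## Evaluation

The balanced training data come from an 80/20 stratified split of the
feature table (per-class proportions within one sample).  Reports contain
the 4×4 confusion matrix (rows actual), overall accuracy = trace/N,
Cohen's kappa = (Po − Pe)/(1 − Pe), misclassification rate = 1 − OA,
one-vs-rest precision/recall/F1 per class (zero denominators reported as 0
with a flag), and one-vs-rest ROC and precision-recall curves with
trapezoidal AUC and step-wise average precision (equal scores grouped into
one threshold).  Display rounding is half-up to two decimals.

The four bundled confusion-matrix fixtures reproduce the published
per-class precision/recall/F1 and overall accuracies at printed precision.
Two caveats are handled explicitly rather than silently: the ANN block
reconciles with the standard row=actual convention only after
transposition (the fixture stores the transposed matrix with a note), and
a few printed cells (including a kappa of 0.87501 printed as 0.87) reflect
truncation rather than rounding, so those assertions use a ±0.01 band.
The source's quoted misclassification percentages are inconsistent with
1 − OA of its own matrices and are not used as targets.

## Problem sizes

Default end-to-end runs use the n = 130 field (above) with tuning budgets
of 6 trials (TPE/grid) and 3-fold CV inside tuning; feature extraction
uses 16 gray levels at distance 1 over four angles.  The full-scale
generator (1266 plots, 964/206/85/11) is exercised for the resampler
count contracts and the tabular property suites; image-based full-scale
runs are supported but not part of the default test conditions.

## Known limitations

* The synthetic texture model is a minimal three-component stand-in;
  absolute feature values and accuracies on it do not transfer to field
  imagery.
* Chan–Vese parameters and the small-region threshold are fixed defaults;
  strongly shadowed or low-contrast canopies would need retuning.
* The TPE tuner treats dimensions independently (no joint density), which
  is the usual simplification and is adequate for six dimensions.
* ROC/PR curves require at least one positive and one negative per class
  in the held-out split; classes absent from it raise an explicit error.
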