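# Methods

`facerisk` implements a complete facial-image risk-modeling workflow for the
two-class problem *benign pulmonary nodule vs lung cancer*: feature
extraction from region-masked facial photographs, a perturbation-robust
logistic feature screen, multi-model benchmarking under stratified
cross-validation, a full evaluation battery, Shapley attribution, and
propensity-score matching. Because no public image cohort exists for this
problem, the package ships a seeded synthetic generator that reproduces the
statistical structure the analysis assumes; everything below is exercised
end-to-end on that generator.

## The feature schema

A face is summarized by **124 features**:

* **108 color features.** Nine skin regions — forehead, glabella, nasal
  tip, mandible, left/right zygomatic, left/right cheek, lip — each
  contribute the mean of 12 color channels over the region mask: R, G, B
  (0–255); H, S, V (fractions scaled to 0–255); CIELAB L, a, b (D65; L
  0–100, a/b signed); and BT.601 YCrCb. Names are `color-<C>-<i>` for
  regions 0–7 and `lipcolor-<C>` for the lip. The numeric suffix order
  (forehead = 0 … right cheek = 7) is a package convention; the channel
  scales are config-pinned constants so comparisons stay internally
  consistent.
* **16 texture features.** A gray-level co-occurrence matrix (GLCM) is
  built from the BT.601 luma of the face bounding box (the union of the
  region masks), quantized to 64 levels, at offset distance 1 and the four
  orientations 0°, 45°, 90°, 135°, symmetric and normalized. Each
  orientation yields ASM = ΣP², Contrast = Σ(i−j)²P,
  IDM = ΣP/(1+(i−j)²), and Entropy = −ΣP log P (natural log). All of
  these are overridable through `GLCMConfig`.

Region masks come either from a label-map PNG or from 68 iBUG-ordered
landmarks via a fixed polygon construction (`regions_from_landmarks`). The
anatomical regions are named, not bit-specified, in the facial-diagnosis
tradition, so the package fixes one landmark-anchored geometry with margins
that make the nine masks pairwise disjoint by construction. Face detection
and landmarking themselves are out of scope: landmarks or masks are inputs.

## Synthetic cohorts

`generate_cohort` draws face-like images: a mid-tone base skin color
(RGB 200, 160, 140) with per-subject jitter (SD 8), a lip tone for the lip
region, class-dependent color shifts (e.g. a saturation shift in the
forehead, a hue shift in the lip) applied in HSV, and a zero-mean
Gaussian-smoothed luminance noise field whose kernel width is the texture
knob — wider kernels give smoother texture, lower GLCM contrast and higher
IDM, so texture effects are monotone and analyzable. Masks are the fixed
geometric template the images are painted from, hence ground truth.

`generate_feature_table` skips the image stage and samples the 124-feature
schema directly from class-conditional multivariate Gaussians with block
correlation structure. The default blocks emulate the correlation pattern
reported for real cohorts: strong positive correlation among intra-channel
color features across regions (r = 0.85) and strong negative correlation
between the GLCM-idm and GLCM-con series (within-series r = 0.8, cross
r = −0.75, the largest magnitude that keeps the matrix positive
semi-definite). Features are standardized, so a planted class effect of
1.0 is a per-SD log-odds of 1.0 under equal priors. Missing cells are
injected completely at random; outliers replace a cell with the column
mean ± 8 column SDs, which trips both the |Z| > 3 and the 1.5×IQR rule by
construction. Optional age/sex columns follow the reported cohort
demographics (benign: age ≈ N(46, 13), 43% male; cancer: age ≈ N(64, 10),
55% male).

What the generator does *not* emulate: photorealistic facial anatomy,
illumination/color-constancy artifacts of real acquisition hardware,
device drift, or demographic covariates beyond age and sex. Passing tests
therefore validate the pipeline's mechanics and statistical behavior, not
clinical performance on real photographs.

## Preprocessing

Per feature column, fitted on training data only and replayed on held-out
data: columns compatible with normality (D'Agostino–Pearson K² at
α = 0.05; Shapiro–Wilk below n = 50) use |Z| > 3 bounds (sample SD) and
mean replacement/imputation; all others use Q1 − 1.5·IQR / Q3 + 1.5·IQR
bounds (linear-interpolation quartiles) and median replacement. Statistics
are computed on the original column, making the transform idempotent.
Constant columns are flagged degenerate (no outlier possible).

## The feature screen

The screen runs variance filtering, greedy correlation pruning
(|r| > 0.95 drops the later column in canonical order, so the survivor
set is deterministic), then one multivariable logistic regression of class
on the z-scored survivors. Odds ratios are therefore per-SD — raw-unit
ORs would be meaningless for channels with means near 200. The fit is
Newton–Raphson with an optional mild ridge (λ = 1e−4 by default, λ = 0
available) whose penalty enters the observed information from which Wald
SEs are taken; 95% CIs use the fixed factor 1.96.

Elimination criteria: OR outside [0.001, 1000]; CI upper/lower ratio
above 100; anomalous estimates (separation, non-convergence, huge SE);
and optionally a CI crossing 1. Two tiers are reported — "valid"
(stability criteria only) and "significant" (also CI excluding 1) —
because the two are genuinely different populations of features.

**Perturbation robustness is the screen's multiplicity control.** With
~120 candidate features, a marginal Wald test at α = 0.05 alone leaves
≈ α·p ≈ 6 chance significances in every cohort. The robustness filter
refits the model on feature matrices jittered with
N(0, (f·column SD)²) noise and keeps a feature only when its criteria
verdict is identical in every replicate (defaults: f = 1.0, 20
replicates; both configurable, as is the stability fraction). Noise at
the feature's own SD attenuates coefficients by roughly half, so a
feature must stay significant under ~50% attenuation in 20 independent
perturbations — an evidence bar around |z| ≥ 5 that chance significances
do not clear, while genuinely informative effects (per-SD log-odds ≈ 1 at
n ≈ 2000, |z| ≈ 15) always do. Tiny noise (f ≈ 0.01) was measured to
flip no verdicts at all, leaving the ≈ 6 false positives in place; the
package therefore treats the perturbation magnitude as the screen's
specificity dial and defaults it to the operating point at which the
screen reliably recovers exactly the informative features. The whole
screen runs inside a stratified 10-fold CV loop; features selected in at
least half the folds (configurable) form the final core set.

## Models and evaluation

Four classifier families — XGBoost, LightGBM, an RBF SVM with sigmoid
(Platt) probability calibration on inner CV, and sklearn's gradient
boosting — are tuned by exhaustive grid search on mean AUC under
stratified 10-fold CV (ties keep the first grid setting; grids are small
configuration defaults since no canonical values exist) and refit on the
full training set. The stratified 80/20 split allocates per-class test
counts by round-half-up with a global adjustment to ceil(N/5), which maps
a 1275/1024 cohort to exactly 1839/460. One run seed derives the split
seed and per-fold model seeds (`seed·100 + fold`), making every run
bit-reproducible.

Evaluation is implemented from first principles: confusion metrics at
threshold 0.5; AUC by the Mann–Whitney midrank formulation (ties get half
credit, verified against an O(n²) pair count); step-interpolated average
precision; Brier score; equal-frequency calibration bins with the
Hosmer–Lemeshow chi-square; decision-curve net benefit
NB(p_t) = TP/N − FP/N·p_t/(1−p_t) against treat-all/treat-none; and the
DeLong test for paired AUCs via midrank structural components with a
normal reference.

One calibration detail: the classical Hosmer–Lemeshow reference is
χ²(g−2) only when the probabilities were fit on the evaluated data; for a
locked model scored on held-out data the statistic is ≈ χ²(g). The
package defaults to the held-out case (`fitted=False`), under which the
test holds its nominal 5% level on well-calibrated external probabilities
(measured 3.5% over 200 simulations; the g−2 reference over-rejects at
12% there).

## Shapley attribution

Attributions use an interventional (marginal) value function over a
finite background sample: v(S) is the mean model output with coalition
columns taken from the explained row and the rest from the background.
Exact subset enumeration (all 2^p coalitions) is used up to p = 12 and
serves as the oracle; beyond that, antithetic permutation sampling (256
permutations by default) with a reported Monte-Carlo SE. Explanations
default to probability space for cross-model comparability; margin space
is a flag. Pairwise Shapley interaction indices are enumerated exactly,
with main effects on the diagonal so interaction rows sum back to the
per-feature attributions.

## Propensity matching

A logistic model of class on standardized age and binary sex gives
propensity scores; greedy 1:1 nearest-neighbor matching without
replacement runs on the logit scale with a 0.2-logit-SD caliper, minority
class first in descending score order — conventional defaults, all
config-exposed. Balance is reported as standardized mean differences
before and after matching.

## Problem sizes used in the test suite

The suite validates statistical claims at the following scales, chosen as
the smallest at which the Monte-Carlo error is decisively below the
asserted tolerances: screen recovery on 100 seeded cohorts of 2000
subjects each (122 null + 2 planted features, per-SD log-odds 1.0);
DeLong variance against a 20,000-replicate stratified bootstrap at
n = 200; Hosmer–Lemeshow level over 200 simulations at n = 5000; null
cross-validated AUC at 500 subjects per class; matching balance over 50
seeded cohorts of 400. The end-to-end demo runs on images of 96×96 pixels
with 150 subjects per class.

## Known limitations

* The synthetic generator is statistical, not photometric; no claim about
  real-photograph performance follows from these tests.
* The landmark-to-region geometry is one admissible construction; region
  features are comparable only within a fixed geometry version.
* The screen's multivariable fit assumes the post-pruning design is
  well-conditioned; with p approaching n it degrades (the demo pipeline
  falls back to the filtered feature set when the screen returns nothing
  at very small n).
* Group-comparison chi-square is provided as standard Pearson (optional
  Yates); published group-comparison statistics for the clinical cohorts
  are not reproducible from their printed counts and are not targeted.
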