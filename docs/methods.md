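# Methods

## Scope and data model

The pipeline scores diagnostic *panels* — non-empty subsets of eight tumor
markers (CEA, CA19-9, CA125, CA15-3, each measured in pleural-effusion
fluid PE and peripheral blood PB) — for discriminating malignant (MPE) from
benign (BPE) pleural effusion, and trades the panels' cross-validated
accuracy against their test cost. Patient-level data from the original
study are available only on request, so the package ships two substrates:

* a **synthetic-cohort generator** that matches the published group-level
  summaries (sizes, age, gender, per-marker mean/SD), used for everything
  that needs patient-level rows; and
* the **published 20-rung ladder** of per-cost best stacking results
  (`mpestack/data/table2.csv`), used by replay mode for the parts of the
  analysis that are pure arithmetic on printed numbers.

## Cohort synthesis

**Margins.** Marker concentrations are strictly positive and, in most
group-by-marker cells, have SD several times the mean (e.g. BPE PE.CEA:
mean 16.80, SD 105.81). A normal margin is untenable; we use a lognormal
moment-matched per cell: σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2.
SD = 0 degenerates to a point mass.

**Dependence.** Markers are coupled by a Gaussian copula. Because margins
are lognormal, sampling reduces to `exp(μ + σz)` with z drawn from the
latent correlation matrix (eigen-factorized, so exactly-semidefinite
matrices are accepted; eigenvalues below −1e−10 are rejected). The latent
correlation defaults to 0.4 between the PE/PB pair of one analyte, 0.2
between analytes within a fluid, 0.1 otherwise. Published summaries carry
no correlation information: these defaults are plumbing chosen to give
plausible positive dependence, they are configurable, and no exact result
in the test suite or acceptance script depends on them.

**Demographics.** Ages are normal with the group's (mean, SD), resampled
(not clipped) outside [18, 100] — an adult cohort whose BPE age SD of 19.02
would otherwise produce impossible values. Gender is assigned as exact
per-group counts and shuffled, reproducing the published margins exactly.
Region is omitted: the published analysis found no significant regional
difference and excluded it from modelling.

**Determinism.** One `numpy` Generator seeded per call; identical (spec,
seed) pairs give byte-identical CSV output.

**What the generator does not emulate.** Assay detection limits and
censoring, batch/site effects, and — importantly — any distributional
feature beyond the first two moments of each cell. Two consequences are
documented rather than hidden:

* Under moment matching, PB.CA125's two groups end up with nearly equal
  log-means (4.77 vs 4.72), so its rank test is essentially null in
  synthetic cohorts even though the published comparison was significant —
  the published difference lives in distributional features that mean/SD
  alone cannot encode. Tests therefore assert significance for the seven
  location-shifted markers only.
* PE.CEA's synthetic univariate separation (latent AUC ≈ Φ(2.09) ≈ 0.98)
  exceeds the published real-data AUC of 0.902: the synthetic benchmark is
  a property check (discrimination well above chance, stacking competitive
  with its best base learner), not a reproduction of real-data values.

## Baseline comparisons

Continuous variables: two-sided Mann–Whitney U with midrank ties. When the
number of distinct relabelings C(n₁+n₂, n₁) is ≤ 50,000 the p-value is the
exact permutation tail of the midrank U (exact under ties; covers every
pair with ≤ 8 per group); otherwise the tie-corrected normal approximation
with continuity correction. Categorical variables: Pearson χ² when all
expected counts are ≥ 5 — with Yates continuity correction on 2×2 tables,
the convention of R's `chisq.test`, which reproduces the published gender
p-value of 0.002 — otherwise Fisher's exact test (2×2 only; sparse wider
tables raise with advice to merge categories). No multiplicity adjustment
is applied, matching the original analysis.

## Diagnostic models

**Features.** For a panel: log(1 + concentration) per marker (columns in
sorted marker order), age, and a male indicator; label 1 = MPE. The log
transform plus a fold-internal standard scaler keeps the heavy-tailed
markers from destabilizing the linear and kernel learners; tree learners
are unaffected.

**Base learners.** Logistic regression; random forest (100 trees); Gaussian
naive Bayes; RBF SVM wrapped in sigmoid (Platt) calibration fitted on inner
training folds, since stacking needs probabilities and the SVM's decision
values are uncalibrated; XGBoost (60 trees, depth 3, η = 0.3). Each is a
`Pipeline(StandardScaler, clf)` so cross-validation refits preprocessing
per fold. Defaults are fixed and modest so that a full multi-seed benchmark
runs in minutes on one CPU; small per-learner grids tuned by inner-CV AUC
are available via `tune_grids=mpestack.models.DEFAULT_GRIDS` for users who
want them.

**Stacking.** `StackingDiagnosticClassifier` builds a meta-feature matrix
of out-of-fold predicted probabilities (stratified inner split, 3 folds by
default — every meta-feature comes from a model that never saw that row),
fits a logistic-regression meta-learner on the five columns, then refits
the base learners on the full training data for prediction. A class too
small to stratify the inner folds fails loudly. The implementation is
deliberately explicit; scikit-learn's `StackingClassifier` with matching
components serves as an independent cross-check in the test suite.

**Evaluation protocol.** Stratified k-fold (k = 3 default; k = n requests
leave-one-out), out-of-fold scores of all patients pooled into one vector;
a single AUC (Mann–Whitney pair-probability form, computed via midranks)
and one sensitivity/specificity pair at probability threshold 0.5 (a
Youden-optimal threshold is available but off by default, and the threshold
used is recorded in every `PerformanceRecord`). Pooling rather than per-fold
averaging yields one ROC for the whole validation process. All randomness
descends from the caller's seed; the same seed reproduces records exactly.

## Pricing and the ladder

Cost is additive over unit prices: RMB 56.5 per CEA test and RMB 84.0 per
CA test, the same for PE and PB specimens. These two numbers are
back-solved from the two cheapest published rungs and validated against all
twenty published costs (56.5a + 84b is injective over the valid (a, b)
analyte-count pairs, hence exactly 20 distinct costs). Per distinct cost,
the maximum-AUC panel forms a rung; AUC ties break toward fewer markers,
then the lexicographically smaller canonical panel string. Ladder selection
uses one model's records (stacking by convention); passing another model's
records is supported.

## Cost-effectiveness

Costs are min–max regularized over the ladder being scored. (Over all 255
panels the min/max — single cheapest marker 56.5, full panel 617 — coincide
with the ladder's, so the choice of regularization population is inert at
default prices.) The C-score is w·AUC + (1 − w)·(1 − regularized cost);
the sweep evaluates a configurable grid (default 0–0.9 in steps of 0.1,
plus 0.95, 0.99, 1.0), marking per-w argmax and argmin with ties broken
toward the cheaper rung — relevant at w = 0.95 where two rungs sit within
5e−4. Quadrant segmentation splits rungs at the median cost and median AUC
(even counts: mean of the central pair); "high" means strictly above the
median, so exact ties land on the "low" side and are flagged. Scores are
kept at full precision internally and rounded half-away-from-zero to three
decimals only for display, matching the printed 0.928/0.903 convention.
Persona recommendations map representative weights (0.5 budget, 0.95
balanced, 0.99 accuracy-first) to their winning rungs.

## Problem sizes used in checks

The shipped test suite and acceptance script use: the full 319-patient
synthetic cohort across 20 seeds (tests) or 5 seeds (acceptance script) for
the stacking benchmark; 20,000 patients per group for generator moment
recovery; 10,000 for copula rank checks; 1,000 random instances (n ≤ 200)
for the AUC pair-counting oracle; and exhaustive enumeration for every
small-sample exact test. These sizes are the package's own choices for
routine verification; all scale up by argument.

## Known limitations

* Synthetic model metrics are not comparable to published real-data AUCs
  (see cohort-synthesis caveats above); the all-marker synthetic cohort is
  nearly separable, so stacking-vs-base comparisons there are weak tests.
* Fisher's exact path handles 2×2 tables only.
* Prices are a two-parameter configuration, not a scraped price list; no
  currency or inflation adjustment.
* No external validation cohort, calibration analysis, or health-economic
  modelling beyond the C-score (no QALY/ICER).
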