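# Methods

## Problem and data model

The pipeline classifies minute-epoch wrist-actigraphy recordings into
three groups — healthy control (0), depressive (1), schizophrenic (2) —
from the statistical shape of hourly activity alone. A recording is an
ordered series of non-negative integer activity counts, one per minute,
over roughly two weeks. The unit of classification is the *hourly
segment*: 60 consecutive standardized counts belonging to one clock hour
of one subject-day, grouped into four day stages (night 00:00–05:59,
morning 06:00–11:59, afternoon 12:00–17:59, evening 18:00–23:59). Each
day stage gets its own feature-selection run, model and evaluation, on
the premise that sleep-period activity is the most class-discriminative.

## Standardization

Counts are z-scored with the sample standard deviation (denominator
n − 1, consistent with the `sd` feature). Three modes:

- `per-class` (default): μ and σ pooled over all counts of a diagnostic
  class. This is how the reference analysis is described, and it is
  label-leaking: the transform applied to a segment depends on the
  segment's class label. The leak is not subtle — any raw count value
  shared across classes (above all the count 0, which dominates night
  hours) maps to a different exact constant −μ̂_c/σ̂_c per class, giving
  every zero-inflated segment an affine class fingerprint that a tree
  ensemble reads off directly. On synthetic cohorts whose three classes
  are generated from *identical* distributions, the per-class pipeline
  still reaches CV accuracy ≈ 1.0 through this channel alone.
- `global`: one μ, σ for the pooled cohort; affine in the same way for
  every subject, hence leakage-free. All separation-sensitivity checks in
  the test suite use this mode.
- `per-subject`: removes between-subject level differences; useful as a
  robustness check, not part of the reference flow.

A class (or subject, or cohort) with zero variance raises a
degenerate-data error; standardization never silently divides by zero.

## Segmentation

Segments are formed per (subject, calendar date, clock hour); only
groups with exactly 60 samples are kept, and the dropped-hour count is
logged. Padding partial hours would break the "comparable instances"
premise of fixed-length rows. A gap-free cohort of `s` subjects and `d`
days therefore yields `s·d·24` segments, `s·d·6` per stage.

## Features

Each segment maps to 23 time-domain statistics (fixed, versioned column
order in `actimind.features.FEATURE_NAMES`). Conventions that matter:

- **Quantiles** use the positional form: the p-quantile sits at position
  `h = p(n+1)` among the order statistics, linearly interpolated, clamped
  to the extremes when `h < 1` or `h > n`. This is the literal reading of
  the decile/quartile position formulas the feature set is defined by,
  and it differs from the more common `h = 1 + p(n−1)` convention.
  Consequence: the median and the 50% quantile are the same number, so
  two of the 23 columns are perfectly collinear. Both are kept to
  preserve the published feature contract; tree ensembles are indifferent
  to collinear duplicates.
- **Moments**: sd and variance use n − 1; skewness and kurtosis are the
  third and fourth central sample moments normalized by powers of the
  sample sd; kurtosis is non-excess (no −3). Zero-variance segments get
  skewness = kurtosis = 0 so that all-zero night hours still produce
  complete rows; mad, sem and the location statistics are defined there
  anyway.
- **unique** counts distinct values of the standardized segment; within
  a standardization unit the transform is strictly increasing affine, so
  the count equals that of the raw counts.

Every statistic is checked against independent naive-loop
implementations to 1e−10 on 1000 random segments.

## Feature selection (RFE-CV)

Recursive elimination wrapped around the forest, ranking by
impurity-based feature importance and dropping `step` features per
round (default 1) until one remains. The cross-validated accuracy curve
is computed by rerunning the elimination path *inside each stratified
fold* and scoring the held-out part at every visited size — ranking on
the full dataset first and cross-validating afterwards looks similar but
inflates the curve on uninformative data (feature-selection bias), which
the permutation-null test in the suite guards against. The reported
subset is taken from a full-data elimination path at the smallest size
whose mean CV accuracy is within 0.001 (absolute) of the best observed;
the tolerance buys parsimony at a negligible accuracy cost.

The elimination loop defaults to a 100-tree forest for tractability
(23 sizes × 5 folds of fits); the chosen subset can be re-validated
under the full 900-tree configuration (`revalidate=True`).

## Classifier

`RandomForestClassifier` with the fixed study configuration: 900 trees,
`min_samples_split=3`, `min_samples_leaf=6`, `max_leaf_nodes=90`,
`bootstrap=False` (each tree fits the entire training set). Remaining
settings take the conventional defaults — per-split feature subsampling
√(n_features), Gini impurity — and are recorded in the config snapshot.
With bootstrapping off, the only randomness is feature subsampling, so
seed changes perturb held-out accuracy by well under two percentage
points on the standard fixtures. Probability scores are the forest's
mean per-tree leaf class frequencies; argmax ties resolve to the lowest
class index.

## Evaluation

- Per-class precision, recall and F1 from one-vs-rest reductions of the
  3×3 confusion matrix (rows = true class); zero denominators return 0
  with a logged warning rather than NaN, because small night-stage runs
  can produce classes that are never predicted.
- **MCC**: one value per model, computed by summing the one-vs-rest
  TP/TN/FP/FN over the three classes and applying the binary Matthews
  formula to the sums (micro averaging). Note this statistic absorbs
  every class's TN mass: embedding a binary problem among extra empty
  classes changes it, unlike Gorodkin's R_k, which is provided as
  `gorodkin_mcc` for comparison. The summed form is used because it is
  the procedure the reference analysis describes.
- **Cross-validation**: stratified k-fold (default 5) with a fresh model
  per fold; overall accuracy pools correct predictions over all folds and
  therefore always lies between the minimum and maximum fold accuracy.
- **ROC**: one-vs-rest curves over all distinct score thresholds
  (anchored at (0,0) and (1,1)), area by the trapezoid rule.
- The 70/30 split takes `floor(0.7·n)` training segments after a seeded
  shuffle — on 8738 segments this gives 6116/2622. Splitting is
  segment-level by default (matching the reference instance counts);
  subject-level splitting, which keeps all of a subject's segments on one
  side, is available as the leakage-safe option.

## Synthetic cohorts

The generator emulates the qualitative structure of the study data, not
any fitted quantities (no per-class count statistics are published to
calibrate against):

- expected count = group night floor + group amplitude × raised-cosine
  bump over the wake window (06:00–24:00), period 1440 min;
- daytime amplitudes 320/220/130 counts·min⁻¹ (control/depression/
  schizophrenia): control highest, depression similar but weaker,
  schizophrenia lowest, at magnitudes typical of published mean daytime
  Actiwatch counts;
- night floors 4/12/25 and night zero-inflation 0.60/0.35/0.20: patients
  sleep worse (more and likelier nonzero night epochs), controls produce
  mostly zero night epochs — this concentrates class signal in the night
  stage by construction;
- counts are negative binomial (dispersion 1.5) around the subject-scaled
  profile; the schizophrenia group's dispersion parameter is doubled,
  tightening relative variance to mimic its reported "more structured"
  signal;
- per-subject lognormal scale factor (σ = 0.15) for between-subject
  heterogeneity;
- a single `separation ∈ [0,1]` interpolates every group parameter
  between the control values (0: classes statistically identical) and
  the full class-conditional values (1);
- timestamps start at a fixed synthetic date at 00:00 so segment counts
  are exact; one seeded generator drives all randomness.

Not emulated: weekday/weekend structure, medication effects, recording
gaps and device non-wear, symptom-severity gradation within a class, and
autocorrelation beyond the smooth profile (epochs are conditionally
independent given the profile). Passing tests on these cohorts shows the
pipeline machinery is correct and that it recovers class structure of
the assumed kind; it does not certify performance on real recordings.

## Test and acceptance problem sizes

The simulation-based checks use cohorts of 10 subjects per class × 13
days (2340 night segments) for separation sweeps, and 3–5 subjects ×
2–6 days elsewhere; these sizes give stable statistics (binomial sd on
2340 segments ≈ 1 accuracy point) while keeping the suite quick.

## Known limitations

- Per-class standardization is implemented exactly as described and is
  the default, but its label leak (above) means accuracies obtained with
  it should not be read as generalization estimates; use `global` mode
  and subject-level splits for honest evaluation.
- Segment-level CV places segments of one subject in both train and test
  folds; with strong per-subject scale heterogeneity the forest can
  fingerprint subjects, which yields slightly-above-chance accuracy even
  for identically distributed classes (~0.34–0.37 observed at
  separation 0 across seeds, chance 1/3). Subject-level splitting removes
  this channel.
- Only time-domain features; frequency-domain characterization is out of
  scope.
- Hyperparameters are fixed inputs; no search is performed.
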