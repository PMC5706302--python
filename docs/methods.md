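# Methods

## Problem and model

The task is multiclass classification of tumour samples into cancer types
from binary gene-alteration profiles. Two alteration kinds are encoded:

* **SPM** — a gene carries at least one non-silent somatic point mutation
  in a sample: one binary column per gene.
* **CNA** — a gene is amplified or deleted: two binary columns per gene
  (AMP, DEL), set independently, because gain and loss are distinct events
  that need not have opposing effects. Thresholded copy-number input
  (GISTIC-style integers in −2..2) is collapsed to sign only: any positive
  value is an amplification call, any negative value a deletion call;
  distinguishing high- from low-level events enlarges the matrix without
  adding class signal.

Before modelling, matrices are sanitised: all-zero columns (genes never
altered anywhere) and all-zero rows (samples indistinguishable from
healthy tissue) are removed, and within the CNA block duplicated columns
are collapsed — whole-arm events give many genes identical call patterns,
and identical columns are indistinguishable to any classifier. Duplicate
detection is exact equality of binary column vectors; the first column in
matrix order is kept and the report records the mapping. This order of
operations (columns, then duplicates, then rows) is idempotent:
re-sanitising a sanitised matrix is a no-op.

## Classifiers and feature ranking

**SVM-RFE (primary).** One-vs-rest linear SVMs (liblinear via
scikit-learn's `LinearSVC`, fixed `random_state` for determinism). With
per-class weight vectors w₁..w_K, feature *j* is scored
s(j) = ∑ₖ w²ₖⱼ, the lowest-scoring surviving feature is eliminated, and
the model is refit; the ranking is the reverse elimination order. The
multiclass extension of RFE admits variants; the ∑w² one-vs-rest score is
the standard choice and is testable against a brute-force
reimplementation, which the test suite does exactly on small instances.
Score ties are broken towards the earlier column, matching `argmin`
semantics, so the ranking is fully deterministic. The elimination schedule
removes one feature per iteration when fewer than 1,000 features survive
and 10 % per iteration above that; exhaustive one-at-a-time elimination is
quadratic in the feature count and chunking above 1,000 leaves the
small-panel region — where order matters — exact. The SVM cost C can be
tuned once per training set by stratified 10-fold cross-validation over a
user grid (ties towards the smaller, i.e. more regularised, cost; folds
reduced with a warning when the smallest class has fewer than 10 members)
and is then reused across RFE iterations; re-tuning inside the loop would
multiply the cost of every run for little gain on binary features.

**L1 multinomial logistic regression (comparator).** The saga solver with
warm starts along a descending λ grid (default: 100 log-spaced points
spanning a 10² range below the data-derived λ_max at which all
coefficients vanish; λ is the per-sample penalty, C = 1/(nλ)). Feature
selection is the active set — features with any nonzero class coefficient.
Non-convergence at a grid point is recorded on that point and the path
continues.

**Random forest (comparator).** Bagged `sqrt(p)`-feature decision trees
with Breiman-style permutation importance measured on each tree's
out-of-bag samples. Backward elimination drops the least important 20 % of
surviving features per iteration; importances are computed once on the
full feature set and not recomputed after drops (the cited backward-
elimination practice), so the forest is refit per iteration only to track
the out-of-bag error. Default 1,000 trees; tests use smaller forests.

**Random baseline.** Class labels drawn i.i.d. with probabilities
proportional to training-class sizes. Against labels from the same
distribution its expected accuracy is ∑ᵢ pᵢ², the floor every ranked panel
must clear.

## Resampling design

A stratified quarter of the samples is set aside as the holdout before
anything else touches the data; the remaining development set is split
4/5 train : 1/5 test, 50 times by default (20 in the bundled synthetic
studies; see below). Stratification uses largest-remainder rounding per
class — proportional within one sample — with remainder ties resolved
towards the earlier class label. All randomness flows from one master seed
through named `SeedSequence` substreams (one for the holdout draw, one per
repeat), so plans are reproducible and repeats are independent.

Per-class precision and recall use exact counting; a class never predicted
has undefined precision and a class absent from a test split has undefined
recall — both are carried as NaN, flagged, and excluded from cross-repeat
averages rather than silently zeroed, since small classes can vanish from
a 1/5 test split. The support-weighted mean of recall equals overall
accuracy by construction and the suite asserts this identity on every
evaluation. Confidence half-widths over the n repeats are 1.96·sd/√n with
the n−1 sample standard deviation.

Two protocol-level checks mirror the substantive claims: the top-n
predictor set should outperform the (n+1)..2n set, which should outperform
the (2n+1)..3n set; and the combined SPM+CNA matrix should beat either
block alone at fixed panel size.

## Stability selection

Each resampled training set yields a different ranking; the robust panel
consists of features frequently ranked high across them. For each feature
we count the rankings in which it appears within the top *m* (default
m = panel size; the two are independently configurable and recorded), then
take the `panel_size` most frequent. Ties are broken by ascending mean
rank across all rankings, then by feature id — an invented but
deterministic rule, invariant to the order of the input rankings. The
selected panel is evaluated exactly once, on the holdout quarter that no
ranking, tuning step or curve ever saw.

## Synthetic data

The generator emulates the structure of pan-cancer alteration data: K
classes (sample counts may be imbalanced), each with a private set of
informative features drawn Bernoulli(p_signal) for members of that class,
all other entries Bernoulli(p_background); informative features are split
between the SPM and CNA blocks by `signal_split` (round-half-up on the SPM
side), and CNA columns alternate AMP/DEL kinds. Defaults are 6 classes ×
60 samples, 5 informative features per class split evenly, 150 SPM + 150
CNA background features, p_signal = 0.6, p_background = 0.02 — an
alteration floor of a few percent with class-informative genes altered in
a majority of their class, which is the regime where recurrently altered
driver genes live, at a size small enough for repeated end-to-end runs.

What the generator does **not** model: correlated alterations (whole-arm
CNA events produce duplicated columns in real data), per-sample mutation-
burden variation, classes distinguished only by combinations of shared
features, or label noise. Passing the bundled studies therefore shows the
machinery is correct and the protocol sound, not that any particular
accuracy will be attained on real tumour cohorts — with real cBioPortal-
derived matrices (thousands of samples, ~10⁴ features) the same pipeline
applies unchanged with the default 50 repeats and the chunked elimination
schedule.

The bundled studies (test suite and `scripts/acceptance.py`) run this
configuration with 20 resampling repeats and a 30-feature panel
(top_m = 30) across several master seeds, in all three modes. Twenty
repeats keeps a full multi-seed, three-mode sweep fast enough to run
routinely while leaving the frequency counts well resolved. Typical
outcomes: mean planted-feature recovery ≈ 0.9, combined-block holdout
accuracy ≈ 0.95 strictly above the SPM-only (≈ 0.89) and CNA-only (≈ 0.80)
blocks, tier accuracies ordered top > second > third, and the empirical
random baseline within sampling error of ∑pᵢ² = 1/6.

## Numerical and degenerate-input choices

* Binary values are stored as uint8 and cast to float64 for solvers.
* `LinearSVC` uses a fixed random_state and max_iter = 5000; convergence
  warnings on noisy instances are suppressed (the dual coordinate descent
  solution is deterministic regardless).
* An all-zero feature column receives exactly zero weight in every
  one-vs-rest SVM, so constant features are always eliminated first and
  never perturb the relative order of informative features.
* A panel consisting only of uninformative features degenerates to an
  intercept-only model, predicting the majority class.
* Samples present in a label table but absent from the call table are
  carried as all-zero rows until sanitisation drops them.
* Matrix emptied entirely by sanitisation, single-class training sets,
  elimination schedules that would remove every surviving feature, panel
  sizes exceeding the number of ever-selected features, and unknown label
  ids all raise immediately rather than degrade silently.

## Known limitations

* The liblinear one-vs-rest formulation is fixed; Crammer–Singer multiclass
  SVMs and kernel SVMs are out of scope, as are deep models (sample sizes
  in this problem class do not support them) and probability calibration.
* Selection frequencies come with no error control (no per-feature FWER
  bounds); the panel is a ranking artefact validated on the holdout, not
  an inferential statement about each gene.
* Correlated features split their SVM weight, so one of a correlated pair
  can be eliminated early; the stability panel is robust to resampling but
  is not a unique optimum — rerunning with other seeds can yield a
  slightly different, comparably performing panel.
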