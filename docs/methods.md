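# Methods

This note documents the model and procedure choices behind `bioselect`: what
each stage computes, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical decisions taken where
the design was genuinely open.

## Data model

A `ClinicalDataset` is a float matrix (one column per attribute, `NaN` the
internal missing sentinel) plus a 0/1 outcome with the clinically adverse
label (fatal, malignant) encoded as 1.  Categorical and boolean attributes
receive stable integer codes in first-appearance order, recorded in the
column's `FeatureSpec` so encoding is reproducible and CSV round-trips are
exact.  Identifier columns (such as a patient ID) stay in the matrix and are
eligible for selection and pruning exactly like any other column; an ID that
carries no class information is expected to be voted out or pruned rather
than excluded a priori.

## Preprocessing

**Hot-deck imputation.**  Each missing cell is filled from the single most
similar donor record that has the cell observed and shares the record's
class; when no same-class donor exists the most similar donor of any class
is used and logged.  Similarity is Euclidean distance over the columns
observed in both records, with numeric columns temporarily min-max scaled to
[0, 1] (so no column dominates by units) and categorical columns
contributing a 0/1 mismatch.  Distance ties resolve to the lowest row index,
making the procedure deterministic.  Imputation runs once on the full table
before selection by default, mirroring a single-pass preprocessing protocol;
`HotDeckImputer` provides the fold-safe variant (donors restricted to the
training part) for leakage-sensitive analyses.  A record missing every
feature is an error — there is nothing to match on.

**Normalization.**  Min-max to [0, 1] by default.  The fitted per-feature
parameters are returned so held-out folds can be transformed with training
statistics; a zero-range (constant) column maps to the lower bound and is
flagged rather than dividing by zero.

**Information gain.**  Numeric features are discretized into 10 equal-width
bins (codes serve as bins for categorical features); gain is
`H(y) − Σ_b p(b)·H(y | b)` in bits.  The binning rule is a convention, not a
calibrated choice: gain values depend on it, and only the *ranking* is used
downstream (as the pruning tie-break).

## Wrapper fitness

Candidate subsets are scored by the accuracy of a discrete AdaBoost ensemble
(10 rounds) of RBF support vector machines (C = 1, kernel width
1/(n_selected · mean feature variance), i.e. sklearn's `gamma="scale"`).
Boosting and the SVM come from scikit-learn; one adaptation matters: sklearn
normalizes boosting sample weights to sum 1, which silently rescales the
SVM's effective per-sample C by 1/n and collapses the base learner, so the
base SVC rescales its sample weights to mean 1 before fitting.  Boosting
theory uses only relative weights, so this changes nothing about the
ensemble logic.

The default measurement protocol is stratified internal 3-fold
cross-validation on the data given to the selector (resubstitution would let
masks overfit trivially); a stratified holdout split is available as a
cheaper alternative and is what the heavier tests and the acceptance script
use.  Scores are cached by mask bits: a revisited subset costs nothing and
always returns the identical value, which also makes selector runs
deterministic for a fixed seed.  The empty mask scores 0 by definition.

## The three selectors

All three optimize over the unit hypercube; a position maps to a mask by
thresholding at 0.5 (boundary inclusive).  This continuous relaxation keeps
the algorithms' arithmetic meaningful while the objective stays a function
of the binary mask.  Positions are clipped to [0, 1] after every move.

**Differential Evolution** — DE/rand/1/bin with population 100, 20
generations, F = 0.5, CR = 0.9 (canonical settings).  Survivor ties go to
the trial vector so the population can drift across the plateaus the
thresholded encoding creates.

**Lion Optimization** — one pride of 20 resident lions plus 40 nomads, 100
iterations.  Each iteration: (i) hunters are ranked, the best 6 form the
centre wing, the rest alternate left/right; a virtual prey sits at the
hunters' centroid; centre-wing hunters jump uniformly between their position
and the prey, the wings jump through the reflected point `2·PREY − x`
(comparisons applied coordinate-wise, `rand(a, b)` meaning uniform on
`[min(a,b), max(a,b)]`); whenever a jump improves fitness the prey escapes
away from the hunter in proportion to the relative improvement
(ε = 1e-12 guards the division).  (ii) Nomads resample each coordinate with
probability `0.1 + min(0.5, (cost − best_cost)/best_cost)`, cost = 1 −
accuracy.  (iii) Random pride pairs produce two offspring by a
`β ~ N(0.5, 0.1)` blend (the two offspring mirror each other around the
parents' midpoint).  (iv) Offspring and nomads that beat the worst pride
displace it (a displaced pride swaps roles with the promoted nomad, keeping
both population sizes constant), so the pride's worst fitness never drops
during replacement.  The reported result is the best pride ever observed.
Mating is unisex (no sex attribute is tracked) and the original algorithm's
defense/migration/equilibrium phases are out of scope.

**Glowworm Swarm Optimization** — 50 worms, 100 iterations, with the
standard constants ρ = 0.4, γ = 0.6, β = 0.08, n_t = 5, s = 0.03, l₀ = 5.
Each iteration evaluates every worm's mask, updates luciferin
`l ← (1 − ρ)l + γJ` (fixed point γJ/ρ, so luciferin is bounded by
max(l₀, γ/ρ) for J ∈ [0, 1]), then moves each worm a step s toward one
brighter neighbour chosen with probability proportional to luciferin excess.
Neighbourhood ranges start and cap at `0.5·√n` — half the hypercube diagonal,
so early neighbourhoods are non-trivial at any dimensionality — and are
floored at 1e-6 because a range of exactly 0 would freeze a worm forever.
Strictly brighter neighbours only: ties carry zero probability mass in the
selection rule.  Two coincident worms have no defined direction; the move is
skipped.  The result is the mask of the maximum-luciferin worm.

## Ensemble selection

A feature survives the vote iff at least 2 of the 3 selectors chose it.
Pruning then scans surviving pairs in feature-index order; when a pair's
Pearson correlation magnitude exceeds 0.95 (absolute value by default —
strong negative correlation is equally redundant; a signed variant is
selectable), the member with the smaller information gain is dropped, ties
dropping the higher index.  Favoring the higher-gain member is a
deterministic way to resolve "either may be removed" toward relevance.
Correlations use the raw-sums closed form and are computed on the full
preprocessed table; a constant feature's correlation is treated as 0 and
logged.  Pruning is idempotent, the final mask is always a subset of the
majority mask, and no surviving pair exceeds the threshold.

## Classifier

`n` selected inputs → `H = 2n + 1` logistic hidden units → one linear
output, trained against 0/1 targets by full-batch gradient descent on mean
squared error.  Weights and biases initialize uniformly in (−0.5, 0.5);
the learning rate starts at 0.5.  Per epoch: take one momentum step
(coefficient 0.9); if the new MSE exceeds 1.04 × the previous MSE, revert
the step, multiply the rate by 0.7 and zero the velocity; otherwise accept,
and multiply the rate by 1.05 when the MSE fell.  These are the canonical
adaptive-rate settings.  Batch updates are required for this rule — an
epoch-level MSE comparison is not well defined for per-sample updates.
Training stops after max_epochs (1000 by default) or when an *accepted*
epoch changes the MSE by less than 1e-6; a rejected epoch leaves the
recorded error unchanged and deliberately does not count as convergence.
Prediction thresholds the linear output at 0.5 (boundary inclusive).  The
sigmoid is evaluated in the numerically stable split form, and analytic
gradients are verified against central finite differences in the tests.

## Evaluation

Accuracy, precision, sensitivity and specificity from pooled confusion
counts over stratified k-fold cross-validation (k = 10 by default, seeded
shuffling; pooled counts always partition the dataset).  Zero-denominator
metrics are reported as undefined, never as 0.  Percentages are rounded to
3 decimals for reporting; published tables for the reference datasets
appear to truncate rather than round, so comparisons against them use a
±0.001 tolerance on the unrounded value.  The default protocol mirrors the
single-pass design (selection on the full preprocessed table, then CV of
the classifier); the `nested` option refits normalization per training fold.

## Synthetic data

The generator draws class-conditional Gaussian features: informative
features have class means ±effect_size/2 and unit variance (so one feature's
Bayes accuracy is Φ(effect_size/2) in closed form); redundant features are a
parent plus N(0, noise_sd) noise with noise_sd = 0.15, giving a realized
parent-child correlation around 0.99 (a spec is rejected if its noise_sd
cannot reach correlation 0.95); noise features are class-independent;
labels are Bernoulli(class_balance).  Missing cells are injected
independently per feature cell, with one record per class protected so
hot-deck imputation always has a complete same-class donor.

What this emulates: the relevant/redundant/irrelevant structure that
selection and pruning are designed for, with analytic accuracy anchors.
What it does not: real clinical tables have mixed types with structured
(non-random) missingness, non-Gaussian marginals, and correlated noise —
passing tests on this generator demonstrates correctness of the machinery,
not clinical performance.

A note on identifiability: a redundant near-duplicate differs from its
parent only by small independent noise, so any accuracy-based selector is
exchangeable between them, and the true information-gain gap between parent
and child is smaller than the gain estimator's sampling noise at a few
hundred rows.  Which of the two survives pruning is therefore effectively
arbitrary; the identifiable property — each informative *signal group*
(parent or duplicate) represented, every duplicate pair broken, no
correlated pair surviving — is what the pipeline guarantees and what the
tests assert.  Strict parent-identity recovery is additionally exercised in
the acceptance suite and documented as not reliably attainable under these
conditions.

## Problem sizes and runtime choices

The library defaults are the full study settings (DE 100×20; LOA 20 prides,
40 nomads, 100 iterations; GSO 50×100; 3-fold internal fitness CV).  The
test suite and the acceptance script exercise the same code paths at
reduced sizes chosen as a deliberate compute budget: selector budgets of
roughly 30×10 to 50×100, the holdout fitness protocol for the heavier
pipeline runs, synthetic tables of 40–4000 rows, and 10-fold CV on 300-row
tables.  Seeds are fixed everywhere; one global seed deterministically
derives all per-stage seeds (31-bit), so identical configurations give
byte-identical reports.

## Known limitations

- Single-pass preprocessing (imputation and normalization before CV) mirrors
  the reference protocol but leaks information across folds; use
  `nested`/fold-safe modes for unbiased error estimates.
- The wrapper fitness carries no parsimony term, so noise features that do
  not hurt held-out accuracy can survive selection.
- The SVM base learner's hyperparameters are fixed (C = 1, scaled RBF); no
  hyperparameter search is performed by design.
- Binary outcomes only; no multi-class support, no ROC/AUC.
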