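# Methods

## The model

`boolfeat` learns classifiers of the form

    logit P(y = 1 | x) = β · Φ(x) + β₀

where `Φ(x)` is a learned *representation*: an ordered list of `p` expression
trees over the raw feature columns.  Each tree is either a raw continuous
feature or a Boolean expression built from threshold comparisons on raw
features (`x_j > θ`, `x_j < θ`) combined with `AND`, `OR`, `NOT`.  Boolean
outputs enter the linear predictor as 0/1 columns, so a fitted model reads as
a short list of weighted clinical rules plus, occasionally, raw continuous
terms.

Comparisons are deliberately leaf-level — a feature against a learned
constant, never one subexpression against another — so thresholds stay in the
raw units of each column (mmHg, mg/dL, encounter counts) and remain readable.

## Threshold learning

Comparison thresholds are learned from the training data by minimizing
weighted Gini impurity over the candidate grid of midpoints between
consecutive distinct values, exactly as a classification tree chooses a split
for a single feature.  Sample weights are the balanced class weights (below),
so rare-class purity counts as much as common-class purity.  Ties are broken
toward the smallest threshold; a degenerate (constant) column raises rather
than returning an arbitrary cut.  Unlike a greedy tree, the surrounding
search is free to keep, discard, or perturb any learned threshold: thresholds
are set when a comparison node is created and may move to an adjacent
candidate midpoint through point mutation, so the population samples the
threshold grid rather than committing to one greedy choice.

## The loss

All fitting and selection uses the balanced logistic loss: cross-entropy with
per-sample weights `N / (2 N_c)` for class `c`, so each class contributes
equal total weight regardless of prevalence.  With ~10% positive cohorts this
stops the fit from collapsing onto the majority class.  The logistic layer is
fit by damped Newton iteration on this loss plus a small ridge penalty
(`1e-6` on coefficients, intercept unpenalized; convergence when the loss
changes by `< 1e-8`, at most 100 iterations).  The ridge term matters in
practice: Boolean derived features frequently separate small internal folds
perfectly, and the penalty keeps those coefficients finite and the solver
deterministic.  Predicted probabilities are clipped to `[1e-12, 1 − 1e-12]`
before taking logs so that no single case can contribute an infinite loss to
lexicase selection.

## The search

A population of `pop_size` representations (default 100) evolves for
`generations` steps (default 100):

1. **Initialization.** Feature-sampling weights are the normalized absolute
   coefficients of per-feature univariate balanced logistic regressions on
   standardized columns.  Half the population are *linear seeds* — 1 to
   `max_dim` bare feature columns sampled by weight without replacement — and
   half are random typed trees of depth ≤ `max_depth` (default 3) whose
   comparison leaves use Gini-learned thresholds.
2. **Selection.** Parents are chosen by epsilon-lexicase selection on the
   per-subject balanced losses of each candidate's fitted model: for each
   parent, the training cases are shuffled and candidates are filtered
   case-by-case, keeping those within ε of the per-case elite, where ε is the
   median absolute deviation of that case's losses over the surviving pool
   (configurable to 0).  This preserves specialists on rare or difficult
   subjects that an aggregate loss would average away.
3. **Variation.** Each offspring comes from exactly one operation — tree
   insertion, tree/subtree deletion, point mutation (AND↔OR swap, comparison
   direction toggle with threshold re-learned, feature resampling, threshold
   perturbation to an adjacent Gini candidate), subtree- or tree-level
   crossover, or correlation deletion (below) — with rates
   (.2, .2, .3, .2, .1).  Offspring that would violate typing, depth, or
   dimensionality constraints fall back to a parent copy (counted in
   diagnostics).
4. **Survival.** An NSGA-II step on the two objectives (training balanced
   loss, representation complexity): fast non-dominated sorting, then
   crowding distance within the last partial front, random tie-breaks from
   the run's seeded generator.  Size is reported but is not an objective.

Every candidate ever evaluated feeds a cumulative Pareto archive of mutually
non-dominated (loss, complexity) pairs; duplicated objective pairs keep their
first representative.  All randomness — splitting, initialization, selection,
variation, tie-breaking, simplification proposals — flows from a single
generator seeded by the config, so a run is exactly reproducible.

Complexity is a recursive weighted operator count, `c(op) = w_op · (1 + Σ
c(children))`, with leaf cost `w_feature`.  The default cost table (feature
and NOT 1; comparisons, AND/OR and +/− 2; other continuous operators 2–4) is
exposed in the config and pinned by the tests; size (split nodes + operator
nodes + feature leaves, a comparison counting as split + leaf) is the
interpretability metric reported to users.

## Internal split and final selection

Before searching, the data is split 80/20 into internal training and
validation sets.  The split is stratified by label — with ~10% prevalence an
unstratified 20% fold has high variance in its positive count, which would
make validation-loss model selection noisy.  After the loop, every archive
member is simplified (next section) and the member with the lowest balanced
log-loss on the validation set is selected (ties: smaller size, then smaller
complexity, then archive order).

Because the search is stochastic, the robust fitting path reruns it
`n_restarts` times (default 10), each restart reseeded so both the internal
split and the search trajectory differ, scores each restart's selected model
by average precision on its own validation split, drops restarts strictly
below the 25th percentile (linear interpolation), and returns the smallest
surviving model (ties: higher average precision, then first-run order).

## Simplification

Evolved trees bloat.  Two mechanisms counter this:

* **Correlation deletion** (also available as a mutation): among all pairs of
  derived-feature columns, find the pair with maximal absolute Pearson
  correlation and delete the member less correlated with the outcome
  (point-biserial; ties delete the later tree).  Boolean columns make this a
  phi coefficient automatically; constant columns are treated as correlation
  zero.
* **Post-run simplification** of final models, three phases of hill climbing:
  (1) exact rewrites to a fixpoint — `NOT(NOT(a)) → a`, duplicate operands in
  serial `AND`/`OR` chains collapsed; (2) iterated correlation deletion;
  (3) iterated uniform subtree deletion (an operator node replaced by one of
  its type-compatible children, or a whole tree dropped), with a proposal
  budget of 5× the model size.  The logistic layer is refit after every
  accepted change.  Non-exact changes are accepted only while the *cumulative*
  mean absolute change in predicted probability on the training set — always
  measured against the pre-simplification model, not the previous step —
  stays within a tolerance (default 0.005).  Deletions of perfectly
  correlated pairs (|r| = 1 within 1e-12) are treated as exact; note their
  refit reproduces the original predictions only to solver precision, since
  the duplicated direction is loss-flat.  Simplification never increases size
  or complexity, and at tolerance 0 only the exact steps fire.

## Decision threshold

The deployed threshold is chosen on the combined internal training and
validation data: scanning distinct score cut-points from low to high, the
first whose prevalence-adjusted positive predictive value

    PPV(ρ) = se·ρ / (se·ρ + (1 − sp)(1 − ρ))

meets the target (default 0.70 at an assumed deployment prevalence ρ = 7.5%)
is returned, which maximizes sensitivity subject to the PPV constraint.  If
no cut-point qualifies the maximizer is returned with a warning.  The
adjustment formula is the standard prevalence re-weighting of sensitivity and
specificity.

## Evaluation harness

AUPRC is average precision and AUROC the normalized Mann-Whitney statistic
(both via scikit-learn; tests cross-check against pair counting and closed
forms).  Two protocols are provided: repeated stratified k-fold
cross-validation of the full pipeline (folds are stratified for the same
prevalence-stability reason as the internal split), and shuffled
75/25-split trials comparing three variants:

* `boolean_simplify` — the full method as described above;
* `onedim` — the same with `max_dim = 1` (a single derived feature);
* `unrestricted` — a legacy-style baseline: the full continuous function set
  (`+ − × ÷ exp log sqrt square relu logistic` in addition to the Boolean
  operators), initial weights from one joint multivariate logistic model, the
  population seeded with that full linear model, no correlation-deletion
  mutation, no post-run simplification, and no tight dimensionality cap.
  The low-dimension constraint, univariate seeding, and simplification are
  themselves parsimony mechanisms, so the baseline that ablates them must not
  keep them.

Variant differences are compared with two-sided Wilcoxon rank-sum tests on
per-(dataset, trial) medians.

## Synthetic data

The generators define the study conditions for all tests:

* **Planted-rule datasets**: standard normal features, optionally in
  equicorrelated Gaussian blocks, labeled either deterministically by a
  single Boolean tree (with optional label-flip noise, and threshold shifting
  to hit a target prevalence) or stochastically through a logistic link over
  several weighted Boolean terms (intercept solved by bisection for the
  target prevalence).  The logistic-link form exists because purely
  deterministic single-rule tasks are representable by one derived feature,
  which would make the single-feature variant artificially competitive; real
  phenotyping targets reward additive evidence across several rules.
  A self-consistency gate (the ground-truth rule classifies its own
  noise-free data with AUROC 1.0) guards every recovery experiment.
* **EHR-like cohorts**: per-subject latent trajectories — 3–8 years of
  encounters, a latent severity driving antihypertensive medication-class
  escalation, blood pressures, a small lab panel, diagnosis-code and
  note-mention counts, and a 10% heart-failure/CKD exclusion flag — are
  labeled by an expert-style apparent treatment-resistant hypertension rule
  applied to the *latent* record: positive if ≥2 of 5 consecutive encounters
  show SBP ≥ 140 or DBP ≥ 90 after ≥30 continuous days on ≥3 medication
  classes, or after ≥30 continuous days on ≥4 classes; negative if the
  exclusion flag precedes qualification.  The emitted table contains only
  summarized columns (per-tier encounter counts as sum/median/SD, BP
  mean/max, lab min/max/median, medication-days, code and note counts, plus
  weakly informative filler labs up to `d`), so features relate to labels
  only statistically — emulating the gap between chart-review truth and
  extracted features.  Default shape is 1200 subjects × 331 columns with
  ~10% prevalence; distributional parameters are calibrated to qualitative
  realism only (plausible vital/lab ranges, <20% of columns dropped by
  preprocessing).  The generator does not emulate free text, coding drift,
  informative missingness, or site effects, so passing tests demonstrate
  correct mechanics and recoverability under honest noise — not clinical
  performance on real records.

## Preprocessing

Columns with fewer than 5% non-zero observed entries or observed variance
below 0.05 are dropped; remaining missing values are imputed with the column
median.  Filters are evaluated before imputation, and both filters and
imputation constants are computed on the full input table before any
splitting — the conventional phenotyping order.  This leaks a small amount of
validation information into the imputation constants; with median imputation
the effect is negligible, but pipelines that need strict separation should
preprocess inside each fold.  An optional per-column (low, high) clamp table
is available for physiologic-range filtering but is off by default, since
such ranges are dataset-specific.

## Problem sizes and numerical choices

Tests and the acceptance script run the search at reduced scale — populations
of 30–100 for 5–40 generations on cohorts of 400–2000 subjects — chosen so
the planted structure is comfortably recoverable; the defaults (100×100)
suit real cohorts of ~1000 subjects.  Other numerical policies: comparisons
are strict (`>`/`<`); Boolean columns encode as 0.0/1.0; protected division
returns 1 where the denominator vanishes; `exp` inputs are clipped at ±20;
Newton steps are halved until the loss does not increase; crowding-distance
ties break by seeded randomness, making whole runs bit-reproducible.

## Known limitations

Greedy Gini thresholds per feature are sampled rather than jointly
re-optimized each generation; the archive keeps the first representative of
tied objective pairs; the robust-selection heuristic is ad hoc (as its
originators note); and interpretability constraints cost discriminative
performance on tasks that genuinely need high-dimensional or longitudinal
structure.
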