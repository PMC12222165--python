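# Methods

This note documents the models and procedures implemented in `roughstack`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Rough-set feature selection

A decision table is a set of objects described by condition attributes and
a categorical decision. The package builds the *decision-relative*
discernibility function: only object pairs with different decisions
generate clauses, since the goal is classification rather than full
indiscernibility analysis. Clause weights are the multiplicity of each
clause among discerning cross-class pairs — the standard data-driven
convention for weighted Johnson reducers. Pairs that differ in decision
but agree on every condition attribute are *inconsistent*: they are
skipped and counted in a diagnostics field rather than raised as errors,
because real clinical tables contain such pairs (rough-set theory handles
them via boundary regions, which are out of scope here).

Johnson's reducer is greedy argmax-by-weight with deterministic
tie-breaking by declared attribute order; the per-step choices and weight
sums are recorded in a selection trace. Its guarantees are those of greedy
set cover: the returned set always hits every clause, its cardinality is
at most `(1 + ln d)` times the minimum (with `d` the largest number of
clauses any single attribute hits), and it is exact when all clauses are
singletons. The exhaustive enumerator of inclusion-minimal reducts exists
for testing and is guarded (default ≤ 20 attributes) because it is
exponential.

**Discretization.** Continuous attributes must be coarsened before
discernibility is meaningful; the default is equal-frequency binning with
3 bins (terciles), which is robust to the skewed ranges of clinical
measurements (cholesterol, ST depression). Equal-width binning and `none`
(for already-discrete tables) are available. Bin edges are recorded in the
table's provenance.

## Scaling, splitting and metrics

Standard scaling uses the population convention (divisor *n*) fitted on
the training split only — R users re-implementing against this package
should note R's `sd()` defaults to *n − 1*. The train/test split is 80:20
by default with `|test| = round(0.2 · n)`, seeded, with optional
stratification (off by default). Metrics are computed from the confusion
counts; undefined ratios (zero denominators) are reported as 0 with a
warning flag on the record instead of NaN, because the downstream
multi-criteria ranking cannot ingest NaN. MAE is the mean absolute error
of the *hard labels*, hence exactly `1 − Ac`; this identity is asserted in
tests. Training time (Tt) is wall-clock seconds, is excluded from every
exact check, and can be pinned to a constant (`fixed_tt`) to make full
pipeline reports reproducible; pinning it makes its ranking weight zero.

## Stacking

Stack memberships are the five fixed lists above; the Pearson-correlation
analysis of the performance matrix (either axis: models across metrics, or
metrics across models) is advisory only and is reported alongside the
definitions. The meta-classifier is logistic regression by default
(configurable per stack), trained on hard 0/1 base predictions; a
probability mode is deliberately not the default since hard labels are
what the literal stacking procedure implies. Both meta-feature modes are
implemented: `cross_fit=False` uses in-sample base-model training
predictions (the literal procedure, optimistically biased because a
memorizing base model hands the meta-learner its own training labels), and
`cross_fit=True` (default) uses stratified 5-fold out-of-fold predictions.
The fitted stack retains the meta-training feature matrix so the
leak-free property can be asserted structurally.

## MEREC and TOPSIS

MEREC normalizes so that *smaller is better* for both directions
(benefit: `min x / x`; cost: `x / max x`), aggregates
`P_t = ln(1 + (1/n) Σ_r |ln n_tr|)` over the *n* criteria, recomputes it
with each criterion removed, and normalizes the total absolute removal
effects into weights. The averaging denominator is the number of criteria,
following the method's original definition (the removal step is otherwise
internally inconsistent). Both methods require strictly positive matrices:
ingest applies an epsilon shift (`1e-6 ×` column max) to zero cells and an
affine shift to negative columns (relevant for MCC in general use), all
recorded in provenance. A constant criterion column receives weight 0
naturally (`|ln 1| = 0`).

TOPSIS uses vector normalization, direction-aware ideal and anti-ideal
points, Euclidean separations, closeness `S⁻/(S⁻+S⁺)`, and ranks by
descending closeness with ties broken by alternative order and flagged.
If all alternatives are identical the closeness is 0/0; the package
returns 0.5 for all with a degeneracy flag. Structural properties asserted
in tests: weights sum to 1 and are non-negative; both methods are
invariant to positive rescaling of any criterion column; closeness lies in
[0, 1]; ranking respects direction-aware dominance. Reversing a
criterion's direction is *not* an involution under these normalizations
and no such identity is asserted.

The criterion directions for the eight canonical metrics are: Ac, Pr, Sp,
Sn, F1, MCC benefit; MAE, Tt cost.

**A documented discrepancy.** The embedded published weight vector for the
five-stack matrix (`table4_weights`) sums to 0.9798 rather than 1 and
cannot be reproduced by this (or, as far as we could determine, any
standard) removal-effect computation from the accompanying performance
matrix: in particular its MCC weight is the smallest although the MCC
column has much the widest spread, which no removal-effect logic produces.
The faithful computation yields a qualitatively different weight pattern
(MAE heaviest, Tt second, vs. the published Tt heaviest, MAE second).
Feeding the *published* weights into this package's TOPSIS reproduces the
published winning closeness to 0.004, which localizes the discrepancy to
the weighting step. The package reports what it computes; the published
vector is kept only as a fixture for comparison.

## Grid-search refinement

Each member of the top-ranked stack is tuned by exhaustive grid search
with stratified k-fold (default 5) cross-validated accuracy; ties break by
grid iteration order, and the search log records one row per
(combination, fold). The winner across members is the highest CV accuracy,
with exact ties falling back to the test metrics lexicographically
(Ac, F1, MCC, −MAE, −Tt). Default grids are small conventional ranges
(tree depths {3, 5, 10, none}, XGBoost learning rate {0.01, 0.1, 0.3} with
L2 {0, 1, 10}, AdaBoost estimators {50, 200}, …) chosen to keep desk-scale
runtime; all are overridable. Only the winning stack is tuned by default,
mirroring the intended flow, though any stack can be passed.

## Synthetic cohorts

The generator emulates a 13-attribute cardiology schema (age 29–77,
resting blood pressure 94–200 mmHg, serum cholesterol 126–564 mg/dl,
maximum heart rate 71–202, ST depression 0–6.2, vessel count 0–4, plus
seven nominal attributes with their coded levels). Numeric attributes are
drawn uniformly within their ranges and nominal attributes uniformly over
their levels; a planted subset of numeric attributes is informative.

The binary outcome follows a logistic model over the informative
attributes' *empirical tercile categories*: each attribute contributes
`effect × s` log-odds with tercile score `s ∈ {−1, 0, 1}`, plus an
intercept of `−effect/2` so no tercile cell sits at probability ½. Risk
that rises in steps across low/middle/high clinical bands is a reasonable
cartoon of categorical risk scoring, and — more importantly — it makes
feature-recovery experiments well-posed: the planted attributes form a
genuine reduct of the tercile-discretized table. Had the effects operated
on the raw continuous values, discretization cells would unavoidably mix
labels, and the true minimal reducts of the discretized table would
provably include noise attributes, making exact recovery impossible for
any method that covers every discernibility clause. Categories are
computed with the same equal-frequency coder the pipeline uses, so
generated cells and analysis bins coincide exactly.

The "strong effect" preset is 20 log-odds per tercile step, i.e.
near-deterministic labels (worst-cell flip probability ≈ 5 × 10⁻⁵); this
is the regime used by the recovery study (n = 1000, 20 seeds), where the
build-time baseline recovery rate is 19/20 seeds within planted-plus-one.
At moderate effects label noise inside cells re-introduces noise-only
clauses and reducts grow — that is a property of exhaustive discernibility
coverage on noisy data, not a bug. The expected positive fraction under
the strong preset is P(Σs ≥ 1) = 10/27 ≈ 0.37.

What the generator does **not** emulate: the inter-feature correlation
structure of real cardiology cohorts (attributes are independent),
measurement noise and missingness, non-uniform marginals, or label
mechanisms involving nominal attributes. Passing recovery tests therefore
demonstrate correctness of the selection machinery under a planted truth,
not expected reduct sizes on real clinical data, where reducts are
typically driven by high-cardinality continuous attributes.

## Numerical and design choices

- Determinism: every stochastic component takes a seed; reports are pure
  functions of (config, seed, input) apart from wall-clock fields.
- Discernibility construction is vectorized over class-pair blocks with
  attribute bitmasks (≤ 63 condition attributes).
- Greedy tie-breaks, CV fold assignment and rank tie-breaks are all
  deterministic and documented above.
- The degenerate inputs policy throughout: empty clause family → empty
  reduct; single-class table → empty discernibility (not an error);
  single-class *training labels* → error; zero-variance scaling column →
  error naming the column.

## Limitations

- Single Johnson reduct only: no boundary regions, rule induction, or
  multi-reduct ensembles.
- Binary decisions only in the modelling layers (the discernibility
  builder itself handles multi-class labels).
- MCDM methods other than MEREC/TOPSIS (AHP, VIKOR, PROMETHEE) and fuzzy
  extensions are out of scope.
- The stacking meta-learner sees only hard base predictions by default;
  probability stacking exists behind a flag but is untuned.
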