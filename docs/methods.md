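# Methods

This note records the models, conventions and deliberate design choices
behind `immunorules`, in the spirit of a statistical software appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## nMFI scoring

Each antigen's scale is anchored at the MFI of a negative and a positive
reference cell population from healthy donors; the interval between them
is divided into ten equal steps. The score of a raw MFI value is

    score = max(0, floor((mfi − neg_ref) / step)),   step = (pos_ref − neg_ref)/10,

so score *k* means "at least *k* full steps above the negative
reference". The rounding rule at bin edges is a convention of this
package (floor, with the exact positive reference mapping to 10 via a
relative 1e-9 edge guard): sources describing the scale do not specify
one. Values below the negative reference clamp to 0 — the scale has no
negative scores — and there is deliberately no upper clamp, because
overexpression on leukemic blasts (scores ≫ 10, e.g. CD10 up to ~164) is
diagnostically meaningful. Scoring is monotone in MFI and invariant under
rescaling all MFIs by a common positive factor; both laws are enforced by
property tests.

## Dataset conventions

- Marker panel: 16 graded antigens (CD34, CD45, CD10, CD38, CD20, CD33,
  CD13, CD22, CD24, CD9, CD15+CD65 — one combined column — CD66c, CD123,
  CD81, cyIgM, TdT) plus binary NG2.
- Missing-data policy: cases with ≥ 50 % missing marker values are
  removed (strict-below retention); the fraction is computed over marker
  columns only, since labels define problems rather than completeness.
  No imputation anywhere. A rule condition evaluated on a missing value
  is **false**, so an incomplete example is covered neither by a rule nor
  by its negation; rule ∪ negation can therefore undercover.
- Per-problem exclusion: a patient missing a label required by a decision
  problem is excluded from that problem only. The *no aberration* primary
  class requires all three labels observed negative; a single positive
  label suffices for the secondary class.

## Rule induction

Candidate elementary conditions are `<`/`≥` tests at midpoints between
consecutive distinct observed values (within the currently covered
examples) for graded markers, and `= 0` / `= 1` for binary ones.

Growth maximizes the C2 measure and proceeds as follows: the opening move
is the best **single condition or condition pair**, found exhaustively;
afterwards conditions are appended purely greedily while they improve
quality by more than 1e-12, stopping early once the rule covers no
negatives. The one-shot pair lookahead is a deliberate design choice:
pure greedy growth is myopic under C2, whose coverage factor
`(P+p)/(2P)` often makes a pure-but-partial single condition outscore
both members of the best pair — growth then stops (the rule is pure) at a
provably suboptimal premise. With the lookahead the grown rule is always
at least as good as any premise of length ≤ 2, a property the test suite
verifies against a brute-force oracle on 100 random small datasets.

Ties between candidates break deterministically: higher quality, then
more covered positives, then attribute name, then smaller threshold, then
relation. Pruning removes non-enforced conditions whose removal does not
decrease quality, repeating until a fixed point; enforced (user-supplied)
conditions are never pruned and never removed.

Sequential covering repeats grow + prune, marking covered positives as
satisfied after each accepted rule (negatives always remain); it stops
when fewer than `mincov` (default 3) positives remain uncovered, or no
rule of positive quality exists. Final rule statistics are re-evaluated
on the full example set.

### Rule statistics

All statistics derive from the 2×2 table `(p, n, P, N)` in which the
rule's own conclusion class plays the primary role, so rules for either
class of a problem are treated symmetrically:

- precision `p/(p+n)`, coverage `p/P`;
- odds ratio `(p/(P−p)) / (n/(N−n))`, reported to two decimals; a zero
  covered-negative cell yields +∞ (rendered "∞ (no covered negatives)"),
  with an optional Haldane–Anscombe +0.5 correction behind a flag;
- significance: the one-sided Fisher exact (hypergeometric tail)
  probability of covering at least `p` positives among `p+n` covered.
  Published significances for the reference cohort match this raw
  one-sided value; which adjustment the original analysis used is
  unstated, so the package reports raw values plus a Benjamini–Hochberg
  adjusted column computed across each induced ruleset;
- the odds-ratio chain evaluates each premise prefix on the full example
  set, tracing how successive conditions concentrate the association.

## Decision trees

Binary recursive partitioning with Gini impurity, grown **best-first**
(the committed split is the largest impurity decrease anywhere on the
frontier) so that the stopping rule is well defined: after every
committed split, Cohen's kappa of the whole tree is evaluated on the
entire training set and growth halts once κ ≥ 0.8 (configurable). Growth
constraints follow rpart conventions: `min_split` 20, `min_leaf` 7,
`max_depth` 30, and `complexity` 0.01 — the minimum split impurity
decrease relative to the root's Gini. The split criterion (Gini) is the
reference default for this algorithm family; the family's sources do not
mandate one. Examples missing the split value follow the branch that
received the majority of observed examples; no surrogate splits (a
simplification, recorded as such). Leaf ties predict the secondary
(majority) class. Grid search enumerates a parameter lattice and keeps
the tree with maximal full-set κ, ties broken by fewer leaves.

## Cross-validation harness

Stratified k-fold CV (default 5) repeated (default 10) with shuffles
derived deterministically from one master seed; all k·reps confusion
matrices are retained. Metrics with zero denominators are recorded as
undefined (NaN) and excluded from means with the exclusion count
reported — they are *not* coerced to 0. F1 is computed per fold and
averaged; pooled-matrix variants are available from the same result
object. Whether a cohort report's dispersions are fold-level or
repetition-level is generally ambiguous; this package reports fold-level
standard deviations. The classifier is a pluggable factory; the bundled
reference backend is LightGBM (gradient boosted trees), chosen because it
tolerates missing values natively, preserving the no-imputation policy.
Its hyperparameters are deliberately ordinary (100 trees, depth 4);
the harness, not the learner, is the contribution. Rank-averaged
importance is the mean 1-based rank position across per-fold models
(gain-based for the reference backend — split counts systematically
undervalue markers, like NG2, that separate a class with a single
split); permutation importance is the mean metric drop over column
shuffles.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any
particular patient:

- class priors 52 : 17 : 124 : 257 (ETV6-RUNX1 : KMT2A : hyperdiploidy :
  none), mutually exclusive by default; a `coaberration_rate` option
  produces double-positives for testing exclusion logic, and
  per-aberration label missingness reproduces differing per-problem
  totals;
- graded scores are discretized log-normals truncated to [0, 200] —
  right skew matches the pooled min/median/max shape, and the family is
  a free choice of this package since only those three statistics are
  available to calibrate against. The location targets the pooled
  median; the spread puts the pooled maximum ≈ 3σ above it; markers
  absent on most blasts carry an extra point mass at 0. Class-conditional
  shifts encode the known associations (high CD10/CD38 and low
  CD34/CD45/CD81 with ETV6-RUNX1; low CD10/CD24/TdT with KMT2A; CD123,
  CD34 and CD66c elevation with hyperdiploidy);
- planted rules (`NG2 = 1 ∧ CD24 ≤ 4 ⇒ KMT2A`, `CD123 ≥ 1 ⇒
  hyperdiploidy`, `CD81 ≤ 4 ∧ CD10 ≥ 98 ⇒ ETV6-RUNX1`) are enforced per
  carrier with penetrance 0.9 by default. The key planted conditions are
  **class-exclusive in the generator** (background NG2 ≡ 0, background
  CD123 ≡ 0, background CD10 capped below 98): real cohorts are noisier —
  manual single-antigen classifiers such as "CD123 ≥ 1 ⇒ hyperdiploidy"
  misclassify many real patients — but exclusivity makes planted-rule
  recovery a well-posed, deterministic property of the induction
  machinery. Passing recovery tests therefore demonstrates correctness of
  the algorithms, not expected performance on clinical data;
- missingness is injected last and never touches labels: per-marker
  independent rates calibrated so eight markers exceed 20 % with a
  maximum of ~36 %, plus a correlated block (CD66c, cyIgM, CD33, CD13,
  CD22, CD9, CD81 jointly missing for 6 % of patients), implemented as
  missing-completely-at-random at the patient level since the true
  mechanism is unknown;
- the true inter-marker dependence structure is unknown, so the generator
  asserts none by default and exposes an optional shared-latent-factor
  `marker_correlation` parameter instead.

## Numerical conventions and degenerate inputs

- Quality-improvement tolerance 1e-12 in growth and pruning.
- Odds ratio of a rule covering no examples, or covering every example,
  is undefined and raises; evaluation records NaN for such premises.
- κ is undefined for a single-class confusion matrix (RAND = 1) and for
  single-class training data (the tree is then a root leaf).
- F1 is 0 by convention when TP = 0.
- `kappa_stop = 0` stops tree growth at the root, since the majority
  classifier's κ is already ≥ 0.
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical configurations reproduce byte-identical outputs.

## Problem sizes used in tests and the acceptance script

Synthetic checks run at n = 300–818 patients (recovery at n = 500,
convergence checks at n = 5000), cross-validation at 5×10 = 50 folds, and
oracle-equivalence checks on 100 random datasets of ≤ 12 rows ×
4 attributes — sizes chosen to make every distributional claim testable
at interactive speed while matching the cohort scale the defaults
emulate.

## Known limitations

- Published cohort-level classification tables (sensitivity/specificity
  per decision problem) require the clinical dataset and are out of
  reach of a synthetic rebuild; the package reproduces instead every
  published rule statistic whose contingency counts are printed.
- One published chain value (16.90 for the full four-condition
  ETV6-RUNX1 tree rule) is not derivable from the printed coverage
  counts by the standard 2×2 odds ratio; the chain operation implements
  the standard definition and does not imitate the printed number.
- The grower's pair lookahead guarantees optimality only against
  premises of length ≤ 2; longer optima may still be missed (inherent to
  sequential covering).
- Rules are descriptive: no voting/conflict-resolution classifier is
  built from rulesets.
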