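# Methods

## The model

`primbox` searches for *boxes*: axis-aligned regions of covariate space
defined by interval bounds on continuous variables and level subsets of
categorical variables, inside which a target function of the outcome is
outstanding. A box `B` is characterised by its **target**
`f(B)` — the arithmetic mean of the outcome on the observations inside it
(or, for censored survival outcomes, the constant-hazard estimate
`sum(events) / sum(observed time)`) — and its **support**
`beta(B)`, the fraction of all observations it contains. The two always
trade off against each other, and the method's output is precisely that
trade-off curve plus a rule for picking a point on it.

### Peeling

Top-down peeling starts from the box containing the whole sample and
repeatedly removes a small marginal subbox. For every continuous variable
the candidates are the `ceil(alpha * n_box)` smallest and the
`ceil(alpha * n_box)` largest in-box values of that variable; for every
categorical variable, each level present in the box; when a variable has
missing values inside the box, the whole missing category is one more
candidate. The candidate whose removal maximizes the target on the
remaining observations is peeled. The *peeling fraction* `alpha` plays the
role of a patience parameter: small values (0.05–0.1) keep single steps
cheap to revise, at the price of more steps. Peeling stops before the box
support would undershoot the *support floor* `beta_min`, so every box of
the recorded sequence — the **trajectory** of (support, target) pairs —
holds at least that share of the data.

Two numerical conventions are fixed here because the mathematical
description leaves them open:

* **Quantile convention.** A continuous candidate removes *exactly*
  `ceil(alpha * n_box)` observations, taken from a stable sort (ties broken
  by row position). This guarantees progress — between 1 and
  `ceil(alpha * n_box)` rows leave the box per step — even on heavily tied
  data, where a threshold-based removal could empty the box or stall.
* **Bounds.** After a peel, the new closed bound sits at the most extreme
  *retained* value, so a printed rule such as `0.23 <= x1 <= 4.94`
  describes the data actually inside the box. Interval membership is
  closed on both sides; the choice only matters for ties.
* **Ties between candidates** resolve deterministically: column order
  first, lower before upper tail, categorical levels in sorted order.

### Pasting

Peeling is greedy and each bound is conditional on all earlier steps, so a
finished box can usually be re-expanded. Pasting enumerates the reverse
candidates — the `ceil(alpha_paste * n_box)` nearest outside observations
beyond one bound (that satisfy the box's other rules), or one excluded
level — and repeatedly applies the target-maximizing one while the in-box
target does not decline. With `paste_lookahead > 0` the search tolerates
that many consecutive declining steps and returns the best box seen, which
lets it cross shallow local dips. By construction the returned box never
has a lower target than its input.

### Multiple peeling, bumping and dominance

A single trajectory depends on `alpha` and on sample noise. The search is
therefore pooled over a grid of alphas and, optionally, over bootstrap
resamples of the data ("bumping"). Boxes found on a resample are
re-evaluated on the original sample before pooling — bumping selects on
the original data, and pooled (target, support) pairs must be comparable.
A box is *dominated* when another pooled box has at least its target with
strictly larger support, or strictly larger target with at least its
support; dominance filtering keeps the Pareto front (one representative
per exact duplicate, earliest in pooling order). The front is the user's
decision surface; the library deliberately has no automatic "knee"
detector, because box choice is a user decision. Two selection policies
bracket the range of user involvement in the simulation study:

* `opt_beta` — maximize the box target subject to a known support floor
  (an optimally informed user; some box always qualifies);
* `fmin` — maximize support subject to a target floor `f_min` (a naive
  user with a fixed effect-size expectation; may conclude "no subgroup").

### Covering

Additional subgroups are found by removing the observations of each
accepted box and re-running the whole search on the remainder. Only
observations are removed, never regions, so later boxes may geometrically
overlap earlier ones; the ordered result is a decision list that predicts
the box target of the first box containing an observation, and the
training target of the uncovered remainder otherwise. Stop criteria
(`max_boxes`, `min_target`, `min_support`) are checked on the reduced
search data, i.e. on the values the box was found with.

### Minimization and survival outcomes

Minimizing the mean target is implemented by sign-flipping the outcome and
back-transforming reported values. The hazard target assumes time-constant
risks within a box; minimization of a hazard has no agreed definition and
is rejected rather than guessed. All-censored data yields a valid all-zero
trajectory plus a warning.

## The CART comparator

The benchmark alternative is binary recursive partitioning: exhaustive
search over (variable, split point) pairs minimizing the summed child
impurity — residual sum of squares for regression, size-scaled Gini for
classification — with midpoint thresholds, level-subset splits after
ordering levels by outcome (exact for RSS and binary Gini), and majority
routing of missing split values. A node splits only while `n >= min_split`,
`depth < max_depth`, both children keep `min_leaf` rows and the impurity
decrease exceeds `complexity_penalty` times the root impurity. Pruning
builds the nested weakest-link cost-complexity path and selects a subtree
by 10-fold cross-validation, at the error minimum (`min_cv`) or by the
one-standard-error rule (`one_se`). Subgroups are read off a tree as the
boxes of its `k` highest-mean leaves; a tree pruned to the root leaf
predicts no subgroup.

Two details of the CV selection were fixed by validating decisions
head-to-head against `rpart` (identical data and fold assignments, via
`xpred.rpart`): exact CV-error ties resolve to the larger complexity value
(the smaller subtree), and the no-split option is evaluated at an
unbounded complexity value so every fold tree collapses — otherwise the
root-leaf candidate competes with a handicap and pure-noise data keeps
spurious splits about twice as often as `rpart` does. Candidate complexity
values are floored at the growing penalty: subtrees the grower would not
have produced are not selection candidates. Surrogate splits are out of
scope; the simulation data has no missing values.

Defaults (`min_leaf = 7`, `min_split = 20`, `complexity_penalty = 0.01`,
10 folds) mirror common recursive-partitioning practice, and the
depth-limited comparator uses depth 4 (one centered subgroup), 8 (two
centered), 2 and 4 for the margin layouts. Exact bit-compatibility with
any particular tree implementation is not a goal; agreement is
Monte-Carlo-level.

## The simulation engine

The data-generating process: six independent covariates
`X1..X6 ~ Uniform(-1, 1)`; one or two axis-aligned squares on `(X1, X2)`
define the true subgroup(s); the outcome is `N(mu, 1)` with `mu = delta`
inside a square and 0 outside, so `delta` is the signal-to-noise ratio.
Square supports are 5/20/40% for one subgroup and 2x5/2x10/2x20% for two.
The exact square positions are fixed here as: centered at the origin;
anchored in the `(+1, +1)` corner (margin layout); two squares centered at
`(-1/2, -1/2)` and `(+1/2, +1/2)` (a diagonal, chessboard-like placement
that is hard for axis-aligned first splits); two squares anchored in the
`(-1, -1)` and `(+1, +1)` corners. Two-square layouts require the square
side `2 * sqrt(beta)` to fit in one quadrant, which all study supports do.

Predicted subgroups are scored on an independent test sample (10,000 draws
by default) by comparing membership in the union of predicted boxes with
true membership: sensitivity, specificity, and Youden's
`J = Sens + Spec - 1`, which is 0 in expectation for a random classifier
and 1 for a perfect one. With `delta = 0` the geometric squares still
define the "positive" rows, so specificity stays defined and detection at
zero effect is a false-positive rate.

Four method variants are compared: `prim_opt_beta` (support floor = true
per-box support, highest-mean selection), `prim_fmin` (target floor
`f_min = 2`, support floor `7/n` to match the comparator's minimum leaf
size, largest-support selection), `cart_maxdepth` (depth-limited tree) and
`cart_pruned` (depth-30 tree, min-CV pruning). Both PRIM variants use the
alpha grid `{0.01, 0.02, ..., 0.5}` with no bootstrap resampling, pasting
off, and covering capped at the true number of subgroups; whether the
original study pasted inside the comparison is not documented, so pasting
is exposed as a flag and off by default. Every replicate draws its seeds
from a deterministic per-cell stream (CRC-derived), so any cell can be
recomputed in isolation.

### What the generator does and does not emulate

The generator reproduces the study conditions exactly: independent uniform
covariates, axis-aligned box-shaped mean shifts, unit Gaussian noise. Real
tabular data has correlated covariates, non-uniform margins, non-box
effects and missing values — none of which the generator produces — so
passing tests certify the search machinery and the published table's
regime, not field performance. The survival generator adds exponential
event times with a planted in-box hazard ratio and independent exponential
censoring whose rate is solved numerically (Brent) to hit a requested
expected censoring share; it emulates time-constant risks only.

## Reported quantities and problem sizes

`scripts/acceptance.py` recomputes detection proportions for selected
table cells at 250 replicates per cell, and the always-detect check for
the floor-free variants at 20 replicates per (layout, support, delta) cell
over the full layout grid and effect sizes {0, 1, 2, 3} — sizes chosen to
keep a full run in the minutes range on one CPU. The test suite uses
reduced replicate counts with 3-standard-error binomial bands.

One benchmarked discrepancy is documented rather than hidden: for the
n=500, 40% support, delta=0.67 cell the published pruned-CART detection
proportion is 0.85, while both this implementation and `rpart` itself
(same settings, min-CV selection) measure about 0.72; the published t4
analogue (0.85 at n=250, 20%, delta=1.33) measures about 0.79 for both.
The comparison with `rpart` bounds what any faithful re-implementation of
the stated recipe can reproduce there.

## Known limitations

* Peeling cost grows with the alpha-grid size times the peel depth;
  the 50-value grid on n=1000 takes ~0.2 s per fit, so quadratic-cost
  usage (bootstraps x alphas x covering rounds) adds up.
* The categorical split search is exact only for RSS and binary Gini
  (ordered-level scan); multiclass categorical splits use the same
  heuristic ordering.
* The hazard target models a single constant rate per box; time-varying
  hazards, Kaplan-Meier or Cox-based targets are out of scope.
* Box overlap is resolved by decision-list order; there is no overlap
  algebra or box-volume computation.
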