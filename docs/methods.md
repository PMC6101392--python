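# Methods

This note records the models the package implements, the assumptions they
make, the parameters that matter, and the numerical and design choices
taken where more than one reasonable option existed.

## Data model

A dataset is a dense samples × genes matrix with exactly two classes.
Internally the minority class is coded −1 and the majority +1 (ties in
class size broken by lexicographic order of the original codes, smaller →
−1), and the minority class is the positive class for TP/FN accounting.
No standard convention exists for which class is "positive" in this
setting; minority-as-positive is this package's choice and is explicit in
every metric function's `positive_class` argument.  Summaries report the
sample-to-dimension ratio SDR = (n₁+n₂)/p (as a percent, rounded half away
from zero) and the imbalance ratio IR = max(n₁,n₂)/min(n₁,n₂) ≥ 1.

Readers accept delimited text (comma/tab auto-detected from the header,
decimal point only, header required), dense ARFF (via `scipy.io.arff`;
sparse ARFF is rejected with a clear message), and MATLAB `.mat` files
with variables `X` and `Y` (via `scipy.io.loadmat`).  Loading rejects
missing values, non-numeric cells, duplicate gene ids, and class counts
other than two, naming the offending row/column.  Delimited output uses
`repr` precision and the loader parses with correctly-rounded `float()`,
so write → load round-trips bit-exactly.

## Random value-based oversampling

RVOS assumes minority samples are i.i.d. draws from a common per-gene
distribution.  A synthetic sample takes, for each gene independently, one
uniform draw (with replacement) from that gene's observed minority values.
Consequences worth knowing:

- every synthetic value exists in the real data (provenance invariant,
  tested exhaustively), but gene–gene correlation within a synthetic
  sample is destroyed by design;
- draws are with replacement because the number of new samples k =
  n_majority − n_minority can exceed the minority count; duplicated
  synthetic rows are possible and permitted;
- a single seeded generator is consumed column-major per new sample, so
  results are reproducible across platforms for a given NumPy generator;
- synthetic rows are appended after the originals with sample ids prefixed
  `synthetic_`, so downstream code can distinguish origin.

Balancing runs on raw values before standardization by default (so
synthetic entries are real measured expression values); pipelines may
reorder.

## The sparse linear SVM

Objective: f(w) = ‖w‖₁ + C Σ_{i∈I(w)} bᵢ², bᵢ = 1 − yᵢwᵀxᵢ, over the
active set I(w) = {i : bᵢ > 0}.  C > 0 is the penalty factor: it
multiplies the loss, so *smaller* C means stronger relative L1 pressure
and sparser w (at C = 10⁻⁹ every weight is exactly 0; the subgradient of
the penalty dominates at the origin).  There is no intercept; the decision
function is sign(w·x) with sign(0) → +1, a measure-zero tie rule.

Training is cyclic coordinate descent in fixed ascending coordinate order
(chosen over random permutations for bit-reproducibility).  At coordinate
j the derivatives of the smooth part at z = 0 are
d₁ = −2C Σ_{i∈I} yᵢx_{ij}bᵢ and d₂ = max(2C Σ_{i∈I} x_{ij}², 10⁻¹²);
the 10⁻¹² floor keeps the one-variable model well-posed when the active
set is empty.  The one-variable piecewise quadratic
|wⱼ+z| + d₁z + ½d₂z² has the exact minimizer

- z = −(d₁+1)/d₂ if d₁+1 ≤ d₂wⱼ,
- z = −(d₁−1)/d₂ if d₁−1 ≥ d₂wⱼ,
- z = −wⱼ otherwise (the coordinate snaps to zero),

derived from subdifferential optimality.  Because the squared hinge is
only once differentiable, the Newton-like step can overshoot; each step is
therefore backtracked (β = 0.5, σ = 0.01, up to 30 halvings) against a
sufficient-decrease condition on the true objective, which makes the
per-sweep objective trace non-increasing by construction — an invariant
the tests assert on random instances.  Margins bᵢ are updated
incrementally after each accepted step (O(n) per coordinate) and recomputed
in full every 50 sweeps to bound floating-point drift.

Stopping: largest accepted step in a sweep < `tol` (default 10⁻⁶) or
`max_sweeps` (default 1000).  Inside the elimination loop the estimator
uses tol 10⁻⁴ and 200 sweeps — rankings depend on weight *order*, which
stabilizes well before the last digits of the weights; the package treats
this as its ranking-precision default.  Convergence is certified by the
subdifferential conditions |d₁| ≤ 1 at zero coordinates and
d₁ + sign(wⱼ) ≈ 0 elsewhere, checked in the tests, and the fitted optimum
is cross-checked against a dense grid-search oracle on tiny instances and
against an independent liblinear formulation of the same objective.

## Variable-step elimination

State: N surviving genes, step S (initially `s_initial`), halving
reference `temp` (initially the total count).  Each iteration deletes
`min(S, N − n_selected)` of the lowest-|w| genes (the clamp guarantees the
run ends at exactly `n_selected` survivors), decrements N by that same
count, and then, while N ≤ temp/2 and S > 1, sets temp ← N and
S ← ⌊S/2⌋.  Three of these choices resolve ambiguities in the obvious
alternatives and deserve a note:

- an exact-equality halving test ("halve when temp/N = 2") can be skipped
  forever by integer steps (temp = 250, S = 12 never lands on N = 125);
  the ≤ form with repeated application implements the intent — halve the
  step whenever the survivor count has halved — for all inputs;
- deleting and decrementing with the *same* count keeps N equal to the
  true surviving-gene count at all times;
- integer halving keeps S a positive integer (25/2 → 12).

With `s_initial = 1` the procedure is exactly classic RFE (asserted
trace-for-trace in the tests).  For 2,000 → 4 genes at `s_initial` = 100
the schedule is 85 fits versus 1,996 for classic RFE; the schedule
arithmetic is verified against an independently written simulator and by a
10,000-triple exact-termination property test.

Ranking: survivors get ranks 1..n_selected by final |w| descending;
eliminated genes follow in reverse elimination order, ordered by |w|
within a batch.  Ties in |w| (common: L1 zeros) are broken by original
column index, higher index deleted first — deterministic on every
platform.  Standardization happens once before the loop; the estimator is
refit from scratch on the surviving columns each iteration (warm starts
are supported by the solver but off by default so iterations are
independent).

## Preprocessing

Standardization is per gene: x → (x − μ)/σ with μ, σ fitted on training
rows only.  σ is the population standard deviation (÷n) by default — the
common machine-scaler convention — with ÷(n−1) available via `ddof`.
Constant genes (σ = 0) standardize to zeros rather than raising, since a
constant gene is uninformative and should not crash a pipeline.
Discretization maps x to +2 (over-expressed) when x > μ+σ/2, −2
(under-expressed) when x < μ−σ/2, else 0, with strict inequalities so
boundary values map to 0.  Thresholds come from whatever params are
passed; the documented default is to discretize the standardized matrix
(μ = 0, σ = 1).  Discretization exists for mutual-information selectors,
which consume it; it is not used by the SVM path.

## Metrics and cross-validation

ACC = (TP+TN)/total.  MCC uses the standard Matthews numerator
TP·TN − FP·FN over √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); that numerator is the
only one consistent with MCC ∈ [−1, +1], +1 exactly at perfect prediction
and sign flip under inverted predictions (all asserted).  A zero
denominator factor (all predictions one class) returns 0, the conventional
reading of an otherwise undefined ratio.  AUC is the Mann–Whitney
estimator — the fraction of (positive, negative) pairs where the positive
scores higher, ties credited 0.5 via average ranks — which equals the
trapezoidal area under the ROC curve; tested against brute-force pair
counting.

Stratified k-fold shuffles each class (seeded) and deals samples
round-robin to folds, so per-fold class counts deviate from exact
proportion by at most one sample per class.  Cross-validation fits a fresh
pipeline per fold on training rows only (an instrumented-pipeline test
asserts no held-out sample id ever reaches `fit`) and reports per-fold
metrics plus their unweighted mean, with confusion counts summed.  Grid
search scores every grid point by mean cross-validated ACC, breaking ties
by declared grid order.  The kNN / naive-Bayes / logistic-regression /
linear-SVM baselines enter through the pipeline contract as thin
scikit-learn adapters; they are deliberately not re-implemented.

## Synthetic data

The generator draws noise genes Normal(0, σ²) in both classes and
informative genes Normal(∓effect/2, σ²) by class, so the between-class
mean gap on an informative gene is exactly `effect`.  Defaults: 10
informative genes, effect 2, σ = 1 — strong enough that the pooled cohort
is linearly separable in the p ≫ n regime (which the tests assert), weak
enough that individual genes overlap between classes.  Six canonical
shape presets (22/40×2000 up to 46/51×24481) reproduce the class-count
and gene-count geometry of the most widely used public two-class
expression datasets.  What the generator does *not* emulate: gene–gene
correlation, batch effects, probe-level artifacts, heavy-tailed noise.
Passing tests on this generator therefore demonstrate correctness of the
algorithms under the stated model, not performance on real cohorts.

A measured property worth stating plainly: under the planted-gene
conditions (1,000 genes, 10 informative, effect 2, 30+30 samples, C = 0.5,
initial step 100) elimination recovers on the order of 7 of the 10 planted
genes in the top 10, averaged over seeds.  The shortfall is intrinsic to
the L1 squared-hinge objective at this sample size — the sparse fit can
prefer a small set of correlated noise genes over a weakly redundant true
gene, and an independent solver of the same objective behaves identically
— not an artifact of the elimination schedule or solver tolerance.

## Problem sizes in the test suite

Tests run on instances small enough to be checked against brute-force
oracles: solver optimality on ≤ 6-gene instances against coarse-to-fine
grid search over the weight cube, the one-variable step against a 1-D grid
at 10⁻⁴ resolution, schedule arithmetic up to a few thousand genes, and
recovery/pipeline runs at 1,000 genes or below.  The acceptance script
generates the six canonical shapes at full size (up to 97 × 24,481), where
only summaries and balancing are computed.

## Known limitations

- Binary classes only; multi-class labels are rejected at load.
- No intercept in the linear model; callers wanting one must append a
  constant feature.
- RVOS weakens with very small minorities (the value pool per gene is the
  minority count); with a single minority sample it can only replicate it.
- The best initial step size is dataset-dependent and exposed as a
  parameter, not estimated automatically; grid search over it is the
  supported route.
- Coordinate descent is implemented in pure NumPy; it is fast for tens of
  samples × tens of thousands of genes but is not tuned for large sample
  counts.
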