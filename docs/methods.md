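# Methods

## Problem setting and model

The package operates on a neighborhood decision system: a finite sample
set *U* (rows of the expression matrix), real-valued conditional
attributes *A* (genes), a categorical decision attribute *D* (the class
label), a Minkowski metric Δ and a radius β ≥ 0. The goal is a small
attribute subset (*reduct*) that preserves the decision structure of the
full set, found in two stages: a univariate Fisher-criterion filter that
discards genes with weak class separation, then a greedy rough-set
reduction that removes redundancy among the survivors.

Assumptions worth stating explicitly:

* **Commensurable attribute scales.** A single radius β across genes is
  meaningless unless columns share a scale, so the pipeline min-max
  normalizes every column onto [0, 1] after removing zero-variance
  columns. Z-score scaling and no scaling are available
  (`normalize="zscore" | "none"`), but β must then be chosen with the
  data's units in mind.
* **Inclusive neighborhood boundary.** β(x) = {y : Δ(x, y) ≤ β} uses ≤,
  and distances are compared to β exactly as computed, with no epsilon
  padding. Users should expect boundary sensitivity: a sample at
  distance exactly β is inside.
* **At least two classes, every class nonempty** — enforced at load
  time; the Fisher criterion is undefined otherwise.

## The two dependency measures

For B ⊆ A, the per-class lower/upper approximations give the positive
region Pos_B(D) (samples whose whole neighborhood is label-pure), the
precision ρ = |∪lower| / |∪upper| and roughness r = 1 − ρ. Because every
sample's neighborhood intersects its own class, the upper union is
provably all of *U*; the negative region is always empty and
ρ = |Pos|/|U|.

The default dependency is the roughness-weighted form

    K(B, D) = (1 − ρ) · |Pos_B(D)| / |U| = ρ(1 − ρ) ∈ [0, 0.25].

Note its inverted semantics: K = 0 both when classification is perfect
(ρ = 1) and when it fails entirely (ρ = 0), with the maximum at
ρ = 1/2. It is implemented literally because it is the measure this
method is defined by, and the identity K = ρ(1−ρ) between its two
printed forms is asserted in tests. Since a greedy search on a
non-monotone target can stall or chase K = ρ(1−ρ) plateaus, the
classical monotone dependency K = |Pos|/|U| is exposed as
`dependency="classic"` and is the variant we recommend for routine
use; the package's own recovery study uses it. K(∅, D) ≜ 0 throughout
(no attributes, nothing discernible, empty positive region).

## Greedy reduction

`forward_reduce` freezes the target K_full = K(C, D) on the initial
candidate set once; the per-iteration pool update only removes chosen
attributes from the pool, never changes the target (a drifting target
would make the stop test ill-defined). The loop:

1. core = {a ∈ C : SIG_inner(a, C, D) > ε}, in ascending column order;
   red starts as the core.
2. Repeatedly add the pool attribute maximizing
   SIG_outer(a, red, D) = K(red∪{a}, D) − K(red, D); ties break toward
   the lowest column index, making the whole procedure deterministic.
3. Stop when |K(red, D) − K_full| ≤ ε (*target-reached*), the pool is
   empty (*pool-exhausted*), no candidate moves K by more than ε for 3
   consecutive iterations (*stagnation*, needed because the default K is
   non-monotone), or max_iter additions (default |C|) were made
   (*max-iterations*). The stop reason is always reported.

Greedy additions can be individually redundant in hindsight, so the
result is not guaranteed to satisfy the strict reduct definition (no
member removable without dropping K by more than ε). `verify_reduct`
checks both reduct conditions, and `prune=True` runs a backward pass
deleting attributes whose internal significance is ≤ ε — later picks
are examined first so earlier selections survive ties — which enforces
the no-removable-member condition.

## Parameters, units, defaults

| parameter | default | meaning / rationale |
|---|---|---|
| β (`beta`) | 0.15 | neighborhood radius in normalized [0,1] attribute space; 0.15 keeps single-gene neighborhoods local at n ≈ 60. Dataset-dependent: the one knob worth tuning. |
| ε (`epsilon`) | 1e-5 | significance floor and stopping tolerance; also replaces the exact Step "K(red)=K(C)" equality, which is meaningless in floating point. |
| metric | euclidean | `manhattan` and `pnorm` (p ≥ 1, else the triangle inequality fails) available. |
| `fld_mode` | score | `score` ranks original genes by univariate Fisher score (selection must report real gene identities); `projection` performs the literal eigenproblem projection; `off` skips the filter (pure NRS). |
| M (`top_m`) | 50 | candidate-set size after the filter; logged prominently since results depend on it. |
| k | c − 1 | projection directions; rank(S_B) ≤ c − 1 bounds the informative count. |
| γ (`gamma`) | auto | ridge added to S_W when singular (always the case for T ≫ n): γ = 1e-6·trace(S_W)/T. Deterministic, well-conditioned; γ = 0 used when S_W is numerically full-rank. |
| classifier | linear SVM, C = 1 | standard for high-dimension/small-n; k-NN (k = 5), CART, Gaussian naive Bayes comparators; 10-fold stratified CV, folds reduced with a warning when the smallest class is smaller, leave-one-out via `folds="loo"`. |

Eigenvectors are unit-norm with the sign fixed so the largest-magnitude
component is positive; the Fisher ratio is scale-invariant, so this is a
determinism convention, not a modelling choice.

## Synthetic data generator

`SyntheticSpec` emulates the two-class microarray regime: default 60
samples, 200 genes, 10 informative genes whose class-conditional means
differ by `effect_size` (default 2) within-class standard deviations,
Gaussian noise elsewhere (Student-t with 3 df behind `heavy_tails` for
robustness checks), optional identically-zero columns (to exercise
constant-column removal) and correlated near-duplicate blocks (to
exercise redundancy removal). Labels follow `class_proportions` exactly
via largest-remainder rounding; column order is shuffled so position
carries no signal; generation is deterministic per seed.

What it does **not** emulate: probe-level artifacts, background
correction, batch effects, heteroscedastic per-gene variances,
class-conditional covariance structure beyond the duplicate blocks.
Passing the recovery study therefore shows the pipeline recovers planted
mean-shift signal at realistic n/T — not that it is robust to every
nuisance of real microarray data.

## Numerical choices and degenerate inputs

* Region computation is vectorized boolean algebra over the n×n
  adjacency matrix; tests assert exact set equality against an
  independent nested-loop enumeration (reals to 1e-12).
* A gene with distinct class means and zero within-class variance gets
  Fisher score +inf and ranks first (logged); zero between- and
  within-variance scores 0.
* All class centroids equal ⇒ S_B = 0: `solve_fld` warns and returns
  canonical basis vectors with zero eigenvalues rather than failing.
* Dependency-style queries recompute neighborhoods from scratch; results
  are pure functions of (data, B, β, metric), so repeated runs are
  bit-identical.
* Problem sizes in the test suite and acceptance script (≤ 30 samples /
  ≤ 5 attributes for oracle comparisons, 20 cohorts of 60×200 for the
  recovery study) were chosen so every oracle can be brute-forced
  exactly and the full run stays in the seconds-to-minutes range.

## Known limitations

* Greedy forward search gives no minimality guarantee; exhaustive or
  discernibility-matrix reduct search is out of scope.
* One global radius per run: no adaptive per-sample radii, no fuzzy or
  kernelized similarity.
* β must be re-tuned per dataset; no automatic selection is provided.
* The evaluation harness makes re-analysis of public microarray sets
  possible (CSV/TSV in, gene lists out) but the package ships no
  downloader and no binary-format (CEL) reader.
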