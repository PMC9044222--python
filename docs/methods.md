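# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic generators do and do not emulate, and known
limitations.

## Dependence estimation

**Discrete mutual information** is the plug-in estimate
I(X;Y) = Σ p̂(x,y) log₂(p̂(x,y)/(p̂(x)p̂(y))) over observed joint cells.
Tiny negative round-off is clipped at zero. It satisfies
I = H(X) + H(Y) − H(X,Y) to machine precision and is reported in bits.

**MIC.** For a pair of length-n real sequences, the characteristic matrix
entry (i, j) is the maximal mutual information over axis-aligned i-by-j
grid partitions, normalized by log min(i, j); MIC is the maximum entry over
the admissible set i, j ≥ 2, i·j ≤ B(n) = ⌊n^0.6⌋ (the exponent and the
inclusive budget are configurable). Cuts are only placed between *clumps* —
maximal runs of tied values — so ties are never split across cells, and
logarithms in numerator and denominator share a base, making the ratio
base-free. Entries take a monotone envelope (entry (i, j) maximizes over
grids with at most i columns and at most j rows), which keeps the matrix
consistent between estimator modes.

Two modes are provided:

- **exhaustive** — brute-force enumeration of every grid partition.
  Exponential in n; intended as a ground-truth oracle for n around a dozen,
  where the admissible set collapses to the 2×2 grid and enumeration is
  hundreds of evaluations.
- **approx** — for each row count j, candidate row partitions of one axis
  are fixed and the optimal column partition of the other axis is found
  *exactly* by dynamic programming over clump boundaries (the per-bin
  entropy contributions are additive, so the DP is an exact maximizer for a
  fixed row assignment). Both orientations are computed and combined
  entrywise. When the row axis has at most `clump_factor` cut positions the
  estimator enumerates **all** of its row partitions, which together with
  the exact DP makes the entry exact — the approximate and exhaustive modes
  then agree to machine precision, which is the package's primary
  correctness oracle. At larger n the single near-equal-count
  equipartition of the row axis is used instead, and candidate column cuts
  are coarsened to `clump_factor × i_max` superclumps: the classic
  heuristic regime, where the estimate is a lower bound on the true grid
  maximum. This two-regime design was chosen deliberately: a pure
  equipartition heuristic is *not* exact even at tiny n (the optimal 2×2
  grid frequently uses extreme, non-median cuts), which would leave the
  estimator without a verifiable ground truth.

Numerical notes: B(n) < 4 admits no grid, so the estimator raises below
n = 11 at the default exponent rather than returning 0. Constant inputs
yield an all-zero matrix flagged `constant_input`. MIC(x, x) = 1 requires a
perfectly balanced admissible grid; at odd n with only the 2×2 grid
admissible the maximum is H(⌊n/2⌋/n) < 1, which is a property of the
definition, not an estimator defect. Class labels enter as integer codes on
one grid axis; continuous features are never pre-discretized.

Defaults: `b_exponent = 0.6`, `clump_factor = 15`, base-2 logarithms. The
row-enumeration cap (3000 partitions) only matters in a narrow band of
sample sizes and is a guard, not a tuning knob.

`pairwise_association` splits work across threads by pair and writes each
value into its own slot, so results are bit-identical for any worker count.

## mRMR ranking

The quotient criterion MIQ = V/W is realized greedily: the first pick
maximizes label association; each later step picks
argmax assoc(y; c) / max(mean_{s∈S} assoc(c; s), ε) with ε = 10⁻¹² — the
quotient is undefined at exactly zero redundancy, so fully non-redundant
candidates receive a large finite score and win. Ties break to the lowest
feature index for cross-platform determinism. The literal set-level forms
(V as the mean label association of a set; W as the mean over all ordered
pairs *including* self-terms, so a singleton has W = 1 under MIC) are
exposed separately from the incremental score. Rankings are
prefix-consistent by construction: the greedy path does not depend on K.

The association measure is pluggable: MIC (default) or discrete MI (a
baseline meaningful only for pre-discretized data).

## PSO wrapper

Positions live in [0, 1]^d, one dimension per candidate feature; a position
decodes to {k : x_k > 0.5}. The threshold decoding (rather than stochastic
sigmoid sampling) keeps the fitness a deterministic function of position.
Velocity updates use per-dimension uniform r₁, r₂, inertia ω = 0.9 fixed
across iterations (no schedule), clamping to ±v_max = 4, and position
clamping to [0, 1]. Defaults: 100 particles, 50 iterations, c₁ = c₂ = 2.

The cost α·V_error + β·N_selected/N_all uses α = 0.95, β = 0.05 (validated
to sum to 1). V_error is the mean misclassification rate of a 5-nearest-
neighbor classifier over a 5-fold stratified split that is drawn **once per
run** — re-randomizing folds per evaluation would make the fitness
landscape noisy and the trace non-monotone in expectation. Features are
min-max scaled per training fold before Euclidean distances. An empty
decoded subset is assigned V_error = 1 (cost α) instead of special-casing
the update rules. Subset → error results are cached within a run, which is
purely an optimization: the mapping is deterministic.

Contracts maintained (and tested): the global-best cost trace is
non-increasing; positions/velocities stay in their boxes after every
update; the same seed reproduces the result bit-for-bit; at the optimum
cost = α·V_error + β·|S|/N_all holds to 10⁻¹².

## Preprocessing

Features are dropped when their fraction of exact zeros exceeds
`max_zero_fraction` (default 0.5); zero fractions are computed on the rows
as given, and the pipeline filters *before* oversampling so duplicated rows
cannot change sparsity statistics. Random oversampling appends exact copies
of minority-class rows, drawn with replacement from a seeded generator,
until every class matches the majority count; originals are always
retained. The expression use case assumes inputs are already
log-normalized; no count normalization is performed. Because ranking and
search run on the balanced data, duplicated rows can straddle internal CV
folds — error estimates on heavily oversampled data are therefore
optimistic and should be read as search guidance, not generalization
estimates.

## Evaluation

Subset accuracy uses a stratified k-fold (default 10) RBF-kernel SVC with
C = 1 and gamma = 1/d on min-max-scaled features (scaler fit per training
fold), one-vs-one for multi-class; no hyperparameter tuning happens inside
the harness, so numbers are comparable across selection methods. The fold
seed is recorded in every report. Accuracy is invariant to feature order
and to positive affine rescaling of features (min-max scaling cancels
affine maps exactly; general monotone maps do change the scaled geometry
and are not an invariance of this harness).

Panels are fit by `statsmodels` Logit (Newton/IRLS, tolerance 10⁻⁸, at most
100 iterations); perfect separation is reported via a `converged` flag with
coefficients still returned. The coefficient table carries standard errors,
Wald chi-square statistics ((coef/se)²) and p-values. AUC is the tie-aware
trapezoidal area, identical to the normalized Mann–Whitney U statistic with
half-credit for ties.

## Synthetic generators

Planted datasets draw informative features as class-conditional Gaussians
with means `class_sep` apart (unit variance), redundant features as noisy
strictly monotone (cubic-link) transforms of random informative features,
and noise features as independent standard Gaussians; class sizes follow
`imbalance_ratio` exactly. Functional pairs (linear, quadratic, sine,
checkerboard, independent) exercise the MIC estimator's equitability and
null behavior. The generators emulate effect size, redundancy structure and
imbalance — they do **not** emulate heavy-tailed count noise, batch
effects, gene–gene correlation networks, or dropout, so green tests
demonstrate algorithmic correctness and recovery under controlled signal,
not performance on real expression data.

Problem sizes in the test suite and acceptance script (30-feature searches,
150–200 samples, 3–5 seeds, 15–30 swarm iterations) were chosen as the
smallest scales at which recovery behavior is stable across seeds; all
defaults remain at the full reference configuration.

## Known limitations

- The approximate MIC estimator is a lower bound outside the exact small-n
  regime; its gap to the true grid maximum grows with n and with tight
  clump budgets.
- The MIQ quotient can favor pure-noise features once strong features are
  selected (null MIC is bounded away from zero at moderate n), which is a
  property of the criterion; the wrapper stage exists to prune such picks.
- Wrapper error estimates on oversampled data are optimistic (see above).
- The swarm is a heuristic: no optimality guarantee, and different seeds
  may return different near-optimal subsets of equal cost.
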