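# Methods

This note documents the statistical model behind `copulamodules`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions a user may want to revisit.

## Copula extraction from counts

Sklar's theorem splits a joint CDF into margins and a copula,
F(x₁,…,x_d) = C(F₁(x₁),…,F_d(x_d)).  For continuous data the probability
transform F(X) is uniform and the copula is unique; for discrete spike
counts neither holds.  We therefore use the distributional transform

    G(x, v) = F⁻(x) + v · (F(x) − F⁻(x)),   F⁻(x) = Pr(X < x),

with v ~ U[0,1) independent of x.  Applied with the *empirical* margin of
the same sample, it produces pseudo-observations that are uniform up to
O(1/n) discreteness and map one jitter stream per dataset (fixed by the
seed) through all columns.  Pseudo-observations are clipped to
[10⁻⁶, 1−10⁻⁶] so downstream estimators never see the boundary.

Margins are kept empirical rather than modeled: for the transform this is
exact (no estimation error beyond the sample itself) and requires no
training.  Parametric or flow-based margin models are deliberately out of
scope.

## C-vine decomposition

The joint density factorizes into bivariate conditional copulas arranged in
a C-vine: tree 1 couples a hub variable to all others; tree t conditions on
the first t−1 hubs.  Choices:

- **Root sequence.**  Variables are ordered once, by descending
  Σⱼ |τ(i,j)| (tie-corrected Kendall tau; ties break by index).  The
  ordering is not recomputed per tree: the first hub is the most globally
  dependent neuron, the natural hub for recordings in which a few neurons
  interact with many.
- **Simplifying assumption.**  Conditional copulas are treated as constant
  in their conditioning values, so every tree pools all n observations;
  conditional pseudo-observations come from h-functions of the previous
  tree, h(x|y) = ∂C(x,y)/∂y, computed by numeric quadrature over the
  fitted density grid (estimator-agnostic and testable against closed
  forms; accuracy ≤ 0.02 against the analytic Clayton conditional CDF at
  G = 100).
- **Independence pruning.**  Every candidate edge is tested against the
  independence copula with a two-sample Fasano–Franceschini 2-D KS test
  versus seeded uniform draws (reference size = sample size, capped at
  2000 points per test for large n).  Edges with p > α = 0.05 are flagged
  independent and pass their arguments through unchanged (h(x,y) = x); no
  multiple-testing correction is applied, matching the per-pair rule the
  method is defined with.  The default p-value comes from a Monte-Carlo
  null (500 uniform-vs-uniform draws at the same sample sizes, cached per
  size and deterministic), which keeps the empirical type-I rate near the
  nominal 0.05 at n = 2000 where the classical asymptotic approximation is
  measurably anticonservative (~0.085); the asymptotic and permutation
  p-values remain available.

## Pair-copula density estimation

Two estimators sit behind one contract (density on (0,1)², mean-1 grid at
cell centers (i+0.5)/G, h-functions):

- **Spline coupling flow.**  A stack of coupling layers on [0,1]² with a
  uniform base; each layer transforms one coordinate by a monotone
  rational-quadratic spline whose knot parameters depend on the passive
  coordinate through a linear map over a cosine feature basis.  With a
  uniform base the log-density is the sum of spline log-derivatives, and
  maximum likelihood is full-batch Adam on exact gradients (the spline
  partials are generated symbolically once per process), with per-layer
  global-norm gradient clipping.  Hyperparameters (layers ∈ {2,4}, basis
  units ∈ {32,64}, knots ∈ {4,8,16}) are chosen by random search scored on
  a held-out 10% split; during each candidate's training the parameters
  with the best held-out likelihood are snapshotted (early stopping — the
  overfitting control that keeps a flexible flow flat on independent data),
  and the winning candidate's model is returned as fitted on the 90%
  split.  Defaults: 10 search trials, 300 epochs, learning rate 0.02
  (halved once after two thirds of training); divergence triggers one
  retry at half the learning rate.  Identical seeds give identical models
  on one platform.
- **Histogram fallback.**  A 2-D histogram on the G×G grid, Gaussian-
  smoothed with σ = 1 bin and renormalized to mean 1 exactly.  It is the
  default for tests, pruning-heavy vine fits, and any sample below 200
  points (flows overfit tiny strata).  σ = 1 was fixed by an
  identifiability diagnostic: heavier smoothing (σ = 2) flattens the
  Clayton corner spike enough that Clayton rows become closer in MSE to
  the Frank density than to their own family.

Analytic reference grids for Clayton/Frank/rotations are computed as exact
cell averages from the closed-form CDF (the grid then integrates to 1
exactly).  At tail singularities the cell-center density can exceed the
cell average threefold, so center-evaluated references are not comparable
to discretized estimates; center evaluation remains available.

## Weight matrix

The weight row of a pair is built from the two neurons' count margins.
Each margin contributes a tail profile g(u) = |F⁻¹(u) − u| evaluated on the
grid (quantile in raw count units; the row is normalized at the end, so
units cancel).  The profile vanishes exactly when the quantile function is
the identity — a uniform continuous margin carries no tail information —
and grows toward u = 1 for skewed count margins.  The outer product
g_x ⊗ g_y is summed with its three quarter-turn rotations (so all four
corners of copula space are emphasized, not only the upper-right), smoothed
with a Gaussian window of σ = 5 bins, floored at 10⁻³ of its maximum (the
weights must stay strictly positive for the multiplicative updates), and
normalized to max 1.  By construction the row is invariant under 90°
rotation and symmetric when the margins coincide.  An alternative profile
with the quantile rescaled by the maximum support is provided
(`profile="rescaled"`), and any callable (margin, grid) → profile can be
substituted; the raw-unit profile is the default because the rescaled
variant empirically weights the center of the square more than the corners
for Poisson-like margins, defeating the construction's purpose.

## Factorization and model selection

Plain NMF uses the Lee–Seung multiplicative updates for the Frobenius
objective, alternating (the H update sees the freshly updated W), which
guarantees a non-increasing objective; denominators carry a 10⁻¹² floor.
The weighted variant multiplies both numerator and denominator products
elementwise by V and adds α₁ + α₂·(entry) to the denominators (the
standard L1/L2 multiplicative-update form).  With V ≡ 1 and α = 0 the
weighted path reproduces the plain one bit-for-bit.  Initialization is
seeded uniform random scaled by √(mean(X)/k); final fits use 10 restarts
keeping the lowest objective.

Speckled cross-validation holds out a random scatter of entries per fold
(5 folds, 10% per fold, masks disjoint across folds, never emptying a
row); held-out entries are removed from fitting by zeroing their weight,
and each fold is scored on exactly those entries.  Two scoring choices are
deliberate:

- **Scoring loss = fitting loss.**  Validation error is the V-weighted
  squared error (normalized by summed weights).  Scoring a weighted fit
  with the unweighted loss systematically rewards extra factors that
  "correct" the weighted fit toward the unweighted optimum, biasing rank
  selection upward.
- **Deterministic CV inits.**  Inside CV, factorizations start from an
  NNDSVD initialization (zeros filled with the matrix mean) instead of a
  random draw: a single bad local optimum at one (rank, fold) cell
  otherwise distorts the whole validation curve, and restarts inside CV
  would multiply its cost several-fold.  The public `nmf`/`wnmf` default
  remains seeded random initialization.

α₁ and α₂ are tuned on the same folds when a grid is supplied; the default
grid is {(0, 0)}.

## Synthetic generators

`make_benchmark` reproduces the validation design: for each family
(case 2: Frank θ=6, Clayton θ=5; case 4 adds their 90° rotations; case 6
adds Clayton 180° and 270°), 20 rows are generated by sampling the copula
(20,000 pairs by default), pushing both coordinates through Poisson
quantiles to counts, re-extracting the empirical copula by the
distributional transform, and estimating its density on a 100×100 grid —
so the matrices have 40/80/120 rows.  The default Poisson rate is 20: the
margin must resolve the copula tails for the design to be identifiable at
all.  At rate 2 the margin has ~5 effective levels and the distributional
transform flattens the Clayton corner into uniform blocks (corner cell ≈ 7
versus 87 for the analytic cell average) — no estimator can then assign
Clayton rows to the Clayton density, and the count-quantile coupling
shrinks Kendall τ by ~0.12.  At rate 20 family assignment is exact
(120/120 rows nearest their own family), τ is preserved within 0.03, and
the residual count-discretization structure is too weak to register as an
extra CV component.  Rates are spike counts per bin — rate 20 corresponds
to, e.g., an active cortical neuron in a 200 ms bin — and remain
configurable.

`generate_population` samples a count matrix whose listed neuron pairs are
coupled through parametric copulas along a dependence forest (roots
uniform, children drawn by conditional inversion; rotations handled through
exchangeability), then maps columns through Poisson quantiles.  Cycles are
rejected.  Note that two children of one hub are themselves dependent
(through the hub), as in real functional-connectivity motifs; "unlisted
pairs independent" holds only conditionally on the hub.

What the generators do *not* emulate: calcium-indicator dynamics and
deconvolution artifacts, behavioral covariates, non-stationarity across
trials, and margin families beyond Poisson.  Passing tests therefore show
that the pipeline recovers planted dependence structure from clean
count data of matched size — not that it is robust to real recording
noise.

## Problem sizes used in the test suite

The validation suite runs the 6-copula benchmark at 5,000 samples per
copula (the CV matrix itself is always 120×10,000, so only row noise
changes) with 400 multiplicative-update iterations per CV fit, and the
2-copula weighted-vs-plain comparison at the full 20,000 samples with 10
seeded restarts.  Flow fits in tests use reduced search budgets (1–2
trials, 120–200 epochs); full-fidelity settings are the defaults of
`fit_copula_flow`.

## Known limitations

- The flow conditioner is linear in a fixed cosine basis, not a deep
  network; very sharp conditional structure may need more basis units than
  the default search space offers.
- h-functions are grid-quadrature approximations (error ~1/G near tails);
  deep-tree conditional samples inherit this smoothing.
- The Monte-Carlo independence null assumes uniform margins of the tested
  pairs — exact for distributional-transform pseudo-observations, but not
  for arbitrary data fed to `independence_test` directly.
- Speckled CV's selected rank is reported together with the full curve;
  when the curve is flat past its minimum, judging "adequate
  approximation" may be preferable to trusting the argmin.
- NMF-family objectives are non-convex; module identification is up to
  permutation and scale, and restarts reduce but do not eliminate
  local-optimum variability.
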