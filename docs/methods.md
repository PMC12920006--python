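# Methods

## Estimand

For observed data `O = (W, A, Y)` — covariates `W ∈ R^p`, exposures
`A ∈ R^m`, outcome `Y` — and an axis-aligned region `𝒜` of exposure
space, define `T = 1{A ∈ 𝒜}` and `Q(1, w) = E[Y | T = 1, W = w]`. The
**attributable regional effect** is

    ψ_𝒜 = E[Q(1, W)] − E[Y],

the change in the population mean outcome under a policy that forces
exposures into 𝒜 while preserving each stratum's relative exposure
preferences inside 𝒜 ("relative self-selection"). Identification of a
causal version requires consistency, conditional exchangeability given
W, and positivity `P(A ∈ 𝒜 | W = w) > 0`; these are assumptions about
the application, not quantities the software computes.

## Targeted estimation

Given initial machine-learned fits `Q̂(T, W)` and `ĝ(W) = P̂(T=1|W)`,
the outcome is min–max scaled to [0, 1] and `Q̂` is updated along the
one-dimensional logistic fluctuation

    Q*(ε) = expit(logit(Q̂) + ε·H),   H(T, W) = T / ĝ(W),

with ε chosen so the efficient-influence-function (EIF) score
`(1/n) Σ H_i (Y_i − Q*(T_i, W_i))` vanishes. The score is monotone in
ε, so a bracketing root find on ε ∈ [−10, 10] is used (tolerance
1e−12; a vanishing score at the bracket boundary — degenerate 0/1
outcomes — is accepted as the asymptotic solution; any other
non-convergence raises with diagnostics). The plug-in
`ψ̂ = (1/n) Σ [Q*(1, W_i) − Y_i]` gets its standard error from the
empirical variance of the EIF

    D_i = (T_i/ĝ_i)(Y_i − Q*(T_i, W_i)) + Q*(1, W_i) − Y_i − ψ̂,

with normal-quantile 95% intervals and two-sided Wald p-values. All
reports are back-transformed to the original outcome scale. `Q̂` values
are clipped to [1e−4, 1−1e−4] before the logit; propensities are
clipped to [g_min, 1−g_min], g_min = 0.025 by default.

## Nuisance estimation (super learner)

`Q̂` and `ĝ` are convex ensembles over a base-learner menu — by default
intercept-only mean, (logistic) linear model, elastic net, random
forest (50 trees, min leaf 5) and gradient boosting (50 rounds, depth
3) — with weights from non-negative least squares on out-of-fold
predictions (5 internal folds), normalised to sum to one. Internal
folds are dealt in the lexicographic order of the rows, so predictions
are invariant to row order. Propensity predictions returned for the
training sample are cross-fitted (each from models whose folds exclude
that row). Learner sizes are deliberately modest: they keep a full
cross-validated fit fast on one core, and in the simulation designs
below larger forests did not change the fitted ensembles' behavior
qualitatively. A failing base learner is dropped with a warning; only
an all-learner failure is an error. A constant outcome is handled by
the mean learner, not an error.

## Region search

The tree explores candidate splits `T = 1{A_j ≤ s}` (LE inclusive, GT
strict, so the two children partition the node). Cutpoints come from
unique observed values after rounding to 1 decimal by default; a
quantile strategy is available for very fine-grained exposures. A
candidate is *valid* only if

1. both children contain at least `min_node` observations (default 10),
2. the cross-fitted split propensity satisfies
   `π̂_i ∈ [ε, 1−ε]` for every node row (default ε = 0.01; the
   practically useful range is about [0.001, 0.05]),
3. the targeted mean of the child in the objective direction differs
   from the parent mean with two-sided Wald p < α (default 0.05),
   treating the parent mean as a fixed constant — a deliberate,
   documented simplification,
4. that child's mean actually improves on the parent in the objective
   direction.

In-tree nuisances are fast by design and never used for reported
inference: the outcome sketch is a per-arm linear fit obtained for
*all* cutpoints at once from cumulative X'X/X'y statistics along the
sorted exposure, and the propensity is piecewise-constant on strata
from a depth-2 regression tree of `A_j` on W, with within-stratum
ECDFs giving `P(A_j ≤ s | stratum)` for all s in one pass. Both are
**cross-fitted over two canonical halves of the node**, which keeps the
split test's standard errors honest in small nodes; without
cross-fitting the per-candidate false-validity rate under a null was
several times the nominal level at n ≈ 100.

Among valid candidates the split is chosen by a one-standard-error
rule: the extremal targeted child mean defines the benchmark, and
within one (two-sample) SE of it the candidate with the largest
improving child wins. A plain argmax suffers a winner's curse — it
drifts toward small, noisy children; because any subregion of a flat
optimum has the same true child mean, the argmax scatters the cutpoint
while the one-SE rule settles on the least restrictive, best-supported
boundary. Remaining ties break by exposure column order, then smaller
cutpoint. Recursion passes each child's targeted mean down as that
child's parent mean and stops at `max_depth` (default 3; 2–3 is
usually enough for ≤10 exposures) or when no candidate is valid. The
returned region is the rule conjunction on the path to the leaf with
the extremal handed-down estimate; a root-only tree means "no region
found". An exhaustive mode branches on every valid candidate and picks
the best terminal leaf with the same one-SE selection; it agrees with
the greedy search at depth 1 and is intended for coarse grids only. No
multiplicity correction is applied across candidates within a node —
the cross-validation layer provides the global error control.

## Cross-estimation and pooling

`CVRegionTMLE` splits the data into K folds (default 10 for data
analysis; the simulation studies here use K = 2). For fold k the
region is discovered and `Q̂`, `ĝ` trained on everything except fold
k; predictions are made on fold k alone. If any fold returns the full
space, the overall status is `no_consistent_region` — pooling is only
meaningful when every fold flags a region, and this rule is what drives
the `α^K`-scale false-discovery behavior under a null. Otherwise all
out-of-fold predictions are stacked, one pooled fluctuation is run, and
`Ψ̂_CV` (the K-fold average of per-fold means of `Q*(1,W) − Y`) is
reported with the EIF standard error over all n. Folds are additionally
grouped by their region's *exposure-name signature*; each group gets
its own pooled estimate (fluctuation re-run on the group's stacked
folds), its fold proportion, and per-rule cutpoint summaries
(mean and min–max across folds). One top-level seed drives fold
assignment, learner seeds and any tree randomness through seed-sequence
spawning.

## Synthetic designs

Three generating processes are built in; they define the package's
simulation conditions and ground truth.

**Discrete grid.** `W1 ~ N(37, 3²)`, `W2 ~ N(20, 1)`,
`W3 ~ Bernoulli(0.5)` (age/BMI/sex-like). Exposures live on a 5×5 grid;
cell probabilities follow a multinomial logit in the standardized
covariates whose 25×4 coefficient matrix is drawn once from N(0, 0.5²)
under a fixed, shipped seed and re-drawn (advancing the seed) until
every cell keeps probability ≥ 1e−4 over a reference covariate sample —
population positivity holds by construction. Outcome:
`Y = 0.2·A1² + 0.5·A1·A2 + 0.5·A2² + 0.2·W1 + 0.4·W3 + N(0, 0.1²)`.
The maximizing level rectangle is both exposures at level 5; the
enumeration oracle (exact over cells, Monte Carlo over W) puts its ARE
near 17.4 under the shipped coefficients. Ground truth for any level
rectangle uses the weighted-average identity
`Q_𝒜(1,w) = Σ_{a∈𝒜} μ0(a,w) p(a|w) / Σ_{a∈𝒜} p(a|w)` exactly over
cells.

**Continuous thresholds.** Same covariates; exposure conditional means
are small linear functions of the standardized covariates (coefficients
0.1/0.1/0.1 and 0.1/−0.1/0, zero intercepts — chosen so marginals stay
near standard normal and the outcome thresholds remain interior), noise
bivariate normal with correlation 0.5, exposures rounded to 1 decimal.
Outcome: `Y = 3·1{A1>0.5} + 2·1{A2<−0.2} + 0.2·W1 + 0.4·W2 + N(0,0.1²)`,
with the indicators evaluated on the rounded exposures so the signal
lives on the observed grid (on that grid `A2 < −0.2` equals
`A2 ≤ −0.3`). Ground truth integrates by Monte Carlo over W with
within-draw rejection over `A | W`.

**Null.** `W1 ~ N(50, 10²)`, `W2 ~ N(25, 3²)`, `W3 ~ Bernoulli(0.5)`;
exposures confounded through means `0.3W1+0.1W2+0.2W3` and
`−0.1W1+0.2W2` with the same correlation structure and rounding;
`Y ~ N(0.2·W3, 5²)` — independent of the exposures by construction.

What these generators do *not* emulate: measurement error,
missingness, skewed or heavy-tailed exposure distributions, more than
two exposure coordinates, and exposure–covariate interactions in the
outcome. Passing tests therefore demonstrate correctness of the
machinery under clean conditions, not robustness to everything real
mixtures data can do.

## Evaluation harness and problem sizes

`run_simulation_study` / `run_replicates` generate fresh datasets, run
the full pipeline, and score each replicate against two truths: the
fixed *oracle* region's ARE, and the *data-adaptive* truth — the
oracle-integrated ARE of the region that replicate actually discovered
(taken as the majority fold-group's mean-cutpoint region). Bias, MSE
(`bias² + n−1-denominator variance of the errors`) and CI coverage are
aggregated per sample size; replicates with no discovered region count
toward discovery rates but are excluded from bias/MSE, and their count
is reported.

The shipped study sizes (also used by `scripts/acceptance.py`) are:
null error control with K = 2 and α = 0.05 at n ∈ {200, 500, 1000,
2000} with 100 replicates each and 250 at n = 5000; the continuous
design with 50 replicates at n = 200 and 30 at n = 5000; the discrete
design with 50 at n = 200 and 30 at n = 5000. These counts were chosen
once as single-core-friendly scale-downs of a 300-replicate design;
Monte-Carlo noise on the reported rates is binomial at those counts.

## Numerical and design choices

- Logistic (not linear) fluctuation on the scaled outcome: respects
  bounds; standard targeted-learning practice.
- The split test treats the parent mean as known; its estimation
  uncertainty is ignored. This makes each split test local and simple,
  at the cost of mild miscalibration where parent and child samples
  are small.
- Region equality across folds is defined by exposure-name signature,
  not cutpoints; cutpoints are summarised per group.
- Fold counts: K = 2 in the simulation studies (it matches the null
  study's design and keeps replicate counts affordable); K = 10
  remains the data-analysis default.
- Sample variance uses the n−1 denominator throughout.
- Degenerate inputs: constant outcomes yield exact degenerate
  estimates (SE 0); constant exposure columns yield no candidate
  cutpoints; single-class treatment raises a named error in the
  propensity ensemble and fails positivity checks automatically.

## Known limitations

- Cutpoint identification near a flat optimum is inherently noisy in
  small samples: regions discovered at n ≈ 200 are often subsets or
  slight dilations of the optimum. Their *own* effects are estimated
  nearly unbiasedly (the data-adaptive parameter), but coverage of the
  fixed oracle parameter degrades at small n.
- The tree's honest (cross-fitted) split test is conservative; under a
  strict null, large samples pass a root split in a minority of fits,
  so pooled null estimates exist only for a small share of replicates.
- Oblique regions, unions of rectangles, categorical exposures,
  survey weights and longitudinal structures are out of scope.
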