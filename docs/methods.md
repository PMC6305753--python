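# Methods

## Model

Let x_i be the length-p vector of normalized, transformed OTU abundances for
sample i and y_i the outcome. A generalized linear model g(E(y_i)) = β0 +
x_i'β (identity link for continuous, logit for binary outcomes) is estimated
by minimizing

    (1/n) Σ_i −l(β0, β; y_i, x_i) + Σ_j ρ(|β_j|; λ1, γ) + λ2 β'Ω(α)β

over a standardized design (each column centered, Σ_i x_ij² = n). The two
penalties play distinct roles:

* **Sparsity.** ρ(t; λ1, γ) = λ1∫₀^|t| (1 − x/(γλ1))₊ dx is the minimax
  concave penalty: λ1|t| − t²/(2γ) for |t| ≤ γλ1, constant γλ1²/2 beyond.
  It thresholds like the Lasso near zero but leaves large coefficients
  nearly unbiased; γ → ∞ recovers the ℓ1 penalty, γ → 1 approaches hard
  thresholding.
* **Phylogenetic smoothness.** C(α) has entries exp(−2α·d_ij) with d_ij the
  patristic distance (an Ornstein–Uhlenbeck-type trait-evolution
  correlation); Ω = C⁻¹. The identity

      β'Ωβ = Σ_i (Ω_ii − Σ_{j≠i}|Ω_ij|) β_i² + Σ_{j<k} |Ω_jk| (β_j − s_jk β_k)²,
      s_jk = sgn(−Ω_jk)

  (verified to 1e-10 in the tests) shows the penalty is a weighted ridge
  plus a Laplacian-type term with adjacency −Ω_jk: it pools coefficients of
  phylogenetically close OTUs (prior-driven smoothing) while retaining a
  data-driven ridge component. Off-diagonal entries of Ω decay with
  patristic distance orders of magnitude faster than the corresponding
  graph-Laplacian entries (asserted as a far-pair decay test on a 200-leaf
  simulated tree), so smoothing is local: distant taxa barely interfere.

Special cases: α → ∞ gives Ω → I, i.e. MCP + ridge (Mnet); λ2 = 0 gives
plain MCP; λ2 = 0 with huge γ gives the Lasso. The Laplacian-penalized
comparator (sparsified to a configurable level, 90% by default; unnormalized
Dg − A by default, with the symmetric degree-normalized variant as an
option) is available through the same engine. Coefficients are *not* rescaled to undo the
ridge-type shrinkage: for non-orthogonal designs rescaling inflates variance
and worsens prediction.

### Grouping property

For a block-clique inverse-correlation structure (clique g of size v_g,
diagonal κ_g(v_g−1)Ω_g0, off-diagonal −Ω_g0), within-clique coefficient
differences of the linear-family estimator obey

    |β̂_j − β̂_k| ≤ ξ · (‖y‖₁/n) · √(2(1 − ρ_jk)),

with t = 2λ2·κ_g(v_g−1)·Ω_g0, ξ = max{2γ/(γt−1), (γt+1)/(t(γt−1)), 1/t}
when γt > 1 and ξ = 1/t otherwise, and ρ_jk the empirical predictor
correlation. The test suite checks the bound on 100 random clique designs
(zero violations; the largest observed difference is ~23% of its bound).
Note the *pointwise* within-clique spread is not monotone in λ2 — it can
bump where the active set changes — but the bound is, and the mean spread
across random instances decreases along the whole λ2 ladder; the tests
assert exactly that.

## Algorithms

**Linear family.** Cyclic coordinate descent. With standardized columns the
coordinate update is the closed-form MCP minimizer of (a/2)t² − bt + ρ(|t|),
with a_j = 1 + 2λ2Ω_jj and b_j the partial residual correlation minus the
off-diagonal smoothness pull 2λ2Σ_{k≠j}Ω_jkβ_k. Each scalar subproblem is
strictly convex iff a_j > 1/γ (checked before solving; γ defaults to 3).
The objective is monotone nonincreasing across sweeps (asserted in tests).
Convergence: max_j|Δβ_j| < 1e-4·max(1, max_j|β_j|) over a full sweep, at
most 1000 sweeps. The intercept is never penalized; with centered columns it
equals ȳ. The kernel is numba-compiled; one sweep is O(np + p²).

**Logistic family.** IRLS: each outer step solves a weighted penalized
linear problem in the working response z = η + (y − μ)/w. Probabilities are
clipped to [1e-5, 1−1e-5]; a step is halved (up to 20 times) if the true
penalized objective increases; at most 100 outer iterations; γ defaults to
30. The IRLS weights are floored at min(0.25, 2/γ): with the working
response above, the fixed points solve the exact penalized score equations
for *any* positive weights, so the floor only slows steps near separation
while guaranteeing every scalar MCP subproblem stays convex (without it the
weighted curvature collapses under quasi-separation and the subproblem loses
convexity).

**Path fitting.** λ1 runs over a log-spaced path of 100 values from
λ_max = max_j |x_j'(y − ȳ)|/n (the smallest λ1 with an all-zero λ2=0
solution) down to λ_max·r, r = 0.01 when p > n and 1e-4 otherwise, with
warm starts. Warm-started solutions match cold starts to 1e-5 on test
problems.

**Inversion.** Ω is obtained by solving (C + εI)Ω = I with the smallest
ε ∈ {0, 1e-8, 1e-6, 1e-4} whose residual max-norm is below 1e-6; ε is
recorded. α = 0 (on the tuning grid) makes C rank-one, so a positive ridge
is then unavoidable. Positive off-diagonal entries of Ω — unexpected for
tree-derived correlations — are counted and flagged with a warning, never
clamped. One inversion per α is cached across the (λ2, λ1) sub-grid, which
is the O(p³) part of the budget.

## Tuning

(α, λ2, λ1) are tuned by 5-fold cross-validation; PMSE for continuous
outcomes, AUC (per fold, then averaged) for binary outcomes with stratified
folds. The default α and λ2 grids are {0} ∪ {2⁻⁵, …, 2⁵}. Ties are broken
toward larger λ1, then larger α, then smaller λ2 (sparser, more local
models). Standardization, constant-column screening and the λ1 path anchor
are computed inside each training fold only; fold paths are aligned by path
index. The winning triple is refit on all training samples.

For the linear family the outcome is additionally standardized fold-locally
(predictions back-transformed; the refit coefficients rescaled to the
original outcome units) so that both penalty grids are scale-free — the same
convention glmnet uses for its gaussian family. Without it an outcome living
on the scale of OTU proportions (sd ~ 1e-3) would render the absolute λ2
grid inert. Columns that are constant within a training fold (all-zero rare
OTUs) are dropped fold-locally, with the structure matrix subset to match,
and re-expanded as zero coefficients in reports.

## Synthetic data

The generator emulates a targeted-sequencing study:

* **Tree.** Random Kingman coalescent over p = 200 OTUs (ultrametric,
  exponential waiting times).
* **Counts.** Dirichlet-multinomial: library size ~ negative binomial with
  mean 5,000 and dispersion 25 (a typical targeted-sequencing depth);
  composition ~ Dirichlet(π(1−θ)/θ); proportions = counts / library size.
  Defaults use a log-normal mean-proportion profile (log-sd 1.5, normalized)
  with θ = 0.02 — the skewed rank-abundance shape of real communities, with
  a method-of-moments estimator (`estimate_dm_params`) provided to
  substitute parameters estimated from a user's own count table.
* **Associated OTUs.** The 200 OTUs are partitioned into 20 clusters by PAM
  (BUILD + SWAP, implemented here and checked against exhaustive search) on
  patristic distances. Scenarios: S1 — 12 aOTUs in a single cluster, equal
  effects, same sign (tree informative); S2 — as S1 with magnitudes ~
  Uniform(0.5, 1.5); S3 — 12 aOTUs in 12 distinct clusters; S4 — as S1 with
  half the signs flipped (both tree non-informative). The aCluster is the
  smallest cluster with ≥ 12 members.
* **Outcome.** η_i = β0 + Σ_{j∈A} β_j x_ij on the proportions. Continuous:
  y = η + ε, ε ~ N(0, σ²) with σ calibrated so sd(η)/σ equals the requested
  signal level (1.0/1.5/2.0 = weak/medium/strong); the variance-ratio
  definition is available as a config switch. Binary: β rescaled so
  Σ_{j∈A} var(x_j)β_j² equals the level (5/10/20); a pool of 20× the needed
  size is simulated with β0 centering η, and balanced cases/controls (50+50
  train, 100+100 test) are drawn without replacement. Calibrations are
  exact by construction and asserted to 1e-8.

What the generator does **not** emulate: phylogenetic correlation among the
*abundances* themselves (mean proportions are assigned independently of the
tree — in real data related taxa often share abundance scale), sequencing
error, chimeras, or zero-inflation beyond what the DM produces. Passing
tests therefore demonstrate correct mechanics and the value of
tree-informed pooling when the *signal* is clustered, not a claim about any
particular real community. Effect sizes are equal on the proportion scale,
which concentrates signal variance on the most abundant associated OTUs;
with skewed abundance profiles this makes the comparative advantage of the
smoothness penalty vary considerably between random draws — cross-validation
then sometimes (correctly) selects no smoothing, and the two estimators
coincide on such draws.

## Preprocessing pipeline

For real count tables, in fixed order: (1) flag outlier samples whose
median Bray–Curtis distance to other samples exceeds the mean by 2.5 sd
(threshold configurable); (2) drop OTUs with prevalence < 10% (boundary
retained); (3) GMPR size-factor normalization — per sample, the geometric
mean over other samples of the median count ratio on shared nonzero OTUs
(zero-robust; a sample sharing no OTU with any other is a named error);
(4) winsorize each OTU at its 97th percentile (type-7 quantiles; a global
cap is available); (5) square-root transform; optionally (6) rank-based
inverse-normal transform Φ⁻¹((rank − 0.5)/n) of a continuous outcome, with
average ranks for ties. Every stage logs input/output dimensions and the
removed sample/OTU names.

## Evaluation harness

PMSE (Brier score for probability predictions), R² as squared Pearson
correlation (defined as 0 with a warning for constant predictions), rank
AUC with half-credit ties, selection sensitivity/specificity against the
generating truth (|β| > 1e-8 counts as selected), and coefficient MSE over
all p entries. The benchmark driver tunes every method inside each of the
repeated train/test splits (k-fold or holdout), reports per-split values,
means with standard errors, and two-sided paired Wilcoxon signed-rank
p-values against a reference method (exact distribution for ≤ 25 splits,
normal approximation with continuity correction above; identical paired
values give p = 1). External predictions (e.g. from tools not implemented
here) can be benchmarked by passing a callable instead of a preset name.

## Problem sizes and defaults

The replicate study in the acceptance suite runs ten seeded S1 replicates
at the study's native scale (p = 200, 100 training / 200 test samples,
strong signal) with the full 12×12 (α, λ2) grids and 100-point λ1 paths —
roughly 40 s per replicate on one core with the compiled kernel. Unit tests
use reduced dimensions (p ≤ 50) chosen to keep each oracle comparison
(OLS, sklearn Lasso/logistic, Nelder–Mead, exhaustive PAM, brute-force tree
paths) exact and fast.

## Known limitations

* Only linear and logistic families; no standard errors or inference on
  coefficients.
* The solver targets p in the hundreds (dense Ω; O(p³) inversions per α);
  prevalence-filter first for larger tables.
* The MCP objective is nonconvex: coordinate descent finds a stationary
  point (verified to be a local minimum against random perturbation on test
  problems), not a certified global optimum.
* CV selection among near-tied cells is noisy at n ~ 100; the grid geometry
  (many smoothing cells vs one λ2 = 0 surface) influences how often
  smoothing is selected.
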