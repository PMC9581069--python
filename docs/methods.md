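# Methods

## Model

`hierridge` fits a two-level ridge regression that integrates feature-level
prior information ("meta-features") into high-dimensional prediction.  With
an n × p subject-level feature matrix X (gene expression, methylation
probes, genotypes, ...), an outcome y, and a p × q meta-feature matrix Z
whose row j describes feature j (pathway memberships, probe-to-gene
groupings, prior effect estimates), the estimator solves

    min_{beta, gamma}  (1/2)||y − X beta||²
                     + (lambda1/2)||beta − Z gamma||²
                     + (lambda2/2)||gamma||²,            lambda1, lambda2 > 0.

The first penalty shrinks each feature coefficient toward a
meta-feature-determined mean (Z gamma)_j rather than toward zero, so
features with similar meta-feature profiles borrow strength from one
another; the second penalty ridge-shrinks the meta-feature coefficients
themselves.  Setting gamma = 0 (equivalently lambda2 → ∞, or Z absent)
recovers standard ridge regression, which is why the submodel is always
kept inside the cross-validation search space (see below).

### Single-level reformulation

Substituting phi = beta − Z gamma turns the problem into an ordinary ridge
regression on the augmented design Xt = [X, XZ] with block-diagonal penalty
Λ = diag(lambda1·I_p, lambda2·I_q) and theta = (phi, gamma):

    (1/2)||y − Xt theta||² + (1/2) theta' Λ theta,
    theta_hat = (Xt'Xt + Λ)⁻¹ Xt' y,      beta_hat = phi_hat + Z gamma_hat.

The XZ block's columns are linear combinations of X's columns, so Xt'Xt is
never full rank even when p + q < n; every solve goes through the
regularized system.  Two routes are implemented and cross-checked:

* **Exact solve** (`solve_closed_form`): Cholesky factorization of the
  (p+q) × (p+q) primal system when p + q ≤ n, otherwise the dual/Woodbury
  form theta = Λ⁻¹Xt'(XtΛ⁻¹Xt' + I)⁻¹y, which factorizes only an n × n
  matrix.  The dual route makes the exact solve practical at any p, which
  is why it — not coordinate descent — is the default at all sizes.
* **Cyclic coordinate descent** (`solve_cd`): exact univariate updates in
  block order (phi then gamma), with precomputed-Gram updates when
  p + q ≤ 4n and residual-based updates otherwise.  The objective is
  jointly convex and separable, so the per-sweep objective is nonincreasing
  and the iterates converge to the global minimum.  Convergence is
  *certified*: after the per-sweep coefficient changes fall below
  `tol · max(1, ||theta||_∞)` the solver evaluates the true gradient and
  stops only when ||∇||_∞ ≤ tol · max(1, ||Xt'y||_∞).  A pure
  small-step criterion can stop far from the minimizer at small penalties,
  where coordinate descent's linear rate is slow.  Warm starts (`theta0`)
  make path-following cheap; warm and cold starts reach the same solution.

### Standardization and the intercept

X columns are standardized to mean 0, population variance 1 at model
construction; constant columns are rejected by index.  The XZ block is
*not* re-standardized: the closed-form special cases and the identity
beta = phi + Z gamma hold only on the raw product (the benchmark's
"augmented ridge" comparator is the deliberate exception, below).  An
opt-in `rescale_augmented=True` scales the XZ block to unit variance before
penalizing — since standardized X makes XZ exactly mean-zero this is a pure
column scaling, equivalent to per-column penalties lambda2 · var(XZ_j), and
gamma is reported back on the raw scale so beta = phi + Z gamma still
holds.  For the
Gaussian model y is centered and the intercept is the training mean; for
the binomial model the intercept is unpenalized and profiled out of each
reweighted least-squares step by weighted centering.  Predictions on new
data always apply the stored training transformation.

Sparse X is supported with scale-only standardization (centering would
densify); when X and Z are both sparse, XZ stays sparse unless its density
exceeds 25%.

## Special-design closed forms (`hierridge.oracles`)

Under an orthonormal design (X'X = I_p) block elimination of the augmented
normal equations gives, with b = X'y = (1 + lambda1)·beta_ridge and
t = lambda2(1 + lambda1)/lambda1,

    gamma_hat = (Z'Z + t·I_q)⁻¹ Z' b,
    beta_hat  = beta_ridge + lambda1/(1 + lambda1) · Z gamma_hat.

Three pedagogical instances are exported and used as exactness oracles:

1. **Disjoint groups** (p = 4, two groups of two): each estimate is its
   ridge estimate plus λ* times the within-group sum, with
   λ* = lambda1²/(2·lambda1 + lambda1·lambda2 + lambda2).
2. **Overlapping groups** (p = 3, the middle feature in both groups): with
   λ* = lambda1²/(3·lambda1 + lambda1·lambda2 + lambda2), the shared
   feature's estimate takes the pooled form
   beta2_ridge + λ*(b1 + 2·b2 + b3); the outer features carry the slightly
   asymmetric weights (2+t, 1+t, −1)/(1+t), which reduce to (2, 1, −1) only
   as t → 0.  The simpler symmetric weights sometimes quoted for this case
   do not satisfy the normal equations at finite t; the implementation uses
   the exact elimination above and matches the generic solver to 1e−8.
3. **Orthonormal quantitative Z** (Z'Z = I_q):
   beta_hat = (I + lambda1²/(lambda1·lambda2 + lambda1 + lambda2)·ZZ')·beta_ridge —
   information is borrowed across all features in proportion to the inner
   products of their meta-feature profiles.  The orthonormality of both X
   and Z is verified numerically (1e−10) before the formula is applied.

λ* is nonnegative, vanishes as lambda1 → 0, and is strictly decreasing in
lambda2: stronger shrinkage of gamma means less pooling.

## GLM extension

For binomial outcomes the penalized negative log-likelihood
−l(theta) + (1/2)theta'Λtheta is minimized by IRLS: each outer iteration
solves a weighted two-level ridge problem in the working response using the
same exact solvers, with working weights floored at 1e−5 and a step-halving
safeguard so the penalized objective never increases.  The ½ penalty factor
matches the Gaussian objective, keeping lambda values on one scale across
families.  The Gaussian family run through the same path reduces to a
single weighted least-squares solve and reproduces the closed form; the
logistic fit matches a generic convex minimizer to ~1e−7 on small
instances.  Linear predictors are clipped at ±30 before the logistic
transform, so predicted probabilities are strictly inside (0, 1).

## Penalty tuning (`cross_validate`)

(lambda1, lambda2) are tuned jointly by k-fold CV over a two-dimensional
log-spaced lattice.  Defaults and the reasoning behind them:

* **Paths**: top of each path = 1000 × the largest |column · null-model
  residual| for that block, descending geometrically to 1e−5 of the top,
  20 points per side.  The factor-1000 top makes the heaviest corner
  essentially the null model; the 1e−5 floor keeps the useful range (for
  ridge, roughly sigma²/sigma_beta² per standardized coefficient) inside
  the grid.  Both knobs are exposed.
* **Ridge sentinel**: the lambda2 = ∞ column (meta-feature block dropped
  exactly, not approximated by a large number) is included by default, so
  the two-level CV loss can never exceed standard ridge's on the same
  folds — the mechanism behind "no cost" when meta-features are
  uninformative.
* **Selection**: minimum mean CV loss (MSE for Gaussian, 1 − AUC for
  binomial); ties break toward the lexicographically larger — more
  parsimonious — pair.  A one-standard-error pair is also reported.
* **Leakage**: standardization is refit on the training portion of every
  fold.  Folds are stratified automatically for binomial outcomes; a class
  with fewer members than folds is an error rather than a silent
  single-class fold.

The engine works in the n × n kernel (dual) representation: per fold it
precomputes K1 = XX', K2 = (XZ)(XZ)' and the validation cross-products, so
each grid point costs one n_train × n_train Cholesky solve regardless of p
and q.  For binomial losses each grid point runs IRLS entirely in kernel
space (with the intercept profiled out under the working weights),
warm-starting the linear predictor from the adjacent grid point; heavier
penalties are visited first.  Exact kernel solves have no use for warm
starts in the Gaussian case; warm starts live where they matter, in the
kernel IRLS and in the coordinate-descent path API.

## Synthetic data (`hierridge.simulate`)

The generators produce the three study designs under which meta-feature
integration is evaluated; their defaults are the study conditions, not
tuning knobs.

* Coefficients: beta ~ N_p(Z gamma, sigma_beta²·I_p).  Meta-feature
  informativeness is set through SNR_gamma = gamma'Σ_Z gamma / sigma_beta²
  (Σ_Z = empirical covariance of the realized Z); `solve_sigma_beta`
  inverts this definition exactly (round trip ≤ 1e−12).
* Features: X rows ~ N(0, Σ_X), AR(1) with rho_X = 0.5, generated by the
  exact AR recursion (no p × p factorization).
* **Discrete design**: Z iid Bernoulli(0.2) indicators ("on average 20%
  nonzero" — averages, not per-column quotas; all-zero columns are
  resampled), q = 6, gamma = 0.1·1_6, mu0 = 0.2, sigma_y = 1, Gaussian
  outcome, training n = 400 (default), independent test n = 1000.
* **Continuous design**: Z rows iid N(0, AR1(rho_Z)), rho_Z = 0 by default,
  q = 150, mu0 = 0.5, gamma = 0.01·(1_50, 0_25, 3_25, 1_25, 0_...).  The
  four leading blocks cover 125 entries (100 nonzero); the tail is zero, so
  growing q only adds noise meta-features.  (The pattern is stated in the
  literature with a tail written as 0_{q−150}, which cannot fill the vector
  since the leading blocks sum to 125; the zero-padded reading used here is
  the only consistent one and preserves the design's intent.)
* **Binary design**: the continuous design with
  y ~ Bernoulli{logistic(mu0 + X beta)}, mu0 = 0.5; degenerate single-class
  draws are resampled with a warning.

What the generators deliberately do not emulate: measurement error in Z,
non-Gaussian feature distributions, heteroscedastic noise, confounding, or
real LD/co-methylation structure beyond AR(1).  Passing benchmarks here
shows the estimator exploits mean-level meta-feature signal under the
stated designs; it does not certify performance on any particular omics
dataset.

### Benchmark harness

`benchmark(scenario, methods=..., reps=50)` realizes the scenario with seed
`seed + r` per replication, tunes each method by k-fold CV on the training
half, and scores the independent test set (R² for Gaussian, AUC — the
rank-based Mann–Whitney estimator — for binomial).  Methods:

* `twolevel` — the full 2-D grid (ridge sentinel included);
* `ridge` — standard ridge, 1-D grid, Z ignored;
* `augmented` — a *single*-penalty ridge on [X, XZ] with **all** columns
  standardized per training fold, the glmnet convention.  Without
  restandardizing the XZ block, the single penalty barely shrinks the
  meta-feature directions (their columns have huge norms) and the
  comparator collapses into the two-level model with an effectively
  unshrunk gamma; standardizing the block is what makes "one penalty for
  both blocks" a real constraint.  The exact algebraic statement
  "lambda1 = lambda2 equals single-lambda ridge on the raw augmented
  design" is kept and tested separately (`tied=True`).

External competitors can be scored on identical data through the
`external_predictions` hook (a callable returning test predictions), rather
than being reimplemented here.

### Problem sizes used in the shipped replications

The replication tests and `scripts/acceptance.py` run the discrete design
at n = 400, p = 2000, q = 6, test n = 1000 with 50 Monte-Carlo
replications (10-fold CV, 10-point paths) at SNR_gamma = 1 and 0.001, and
the binary design at n = 400, p = 2000, q = 150 with 50 replications
(10-fold CV, 6-point paths, two-level vs standard ridge).  Fifty
replications with 10-point (Gaussian) / 6-point (binomial) paths give
direction-stable comparisons at a few minutes per design on one core; a
`--reps` flag raises the count for full-scale runs.

## Numerical choices

* All symmetric solves use Cholesky factorizations; no explicit inverses.
* Standardization uses population (1/n) variance; zero-variance tolerance
  1e−12.
* CD convergence tolerance 1e−7 (gradient-certified, see above),
  max 5000 sweeps, with a `RuntimeWarning` and `converged=False` on
  exhaustion — never a silent partial answer.
* IRLS: relative objective tolerance 1e−9, max 100 outer iterations,
  weight floor 1e−5, step halving down to 2⁻¹⁰ before declaring a
  numerical fixed point.
* lambda2 = ∞ is a sentinel that drops the gamma block exactly; a finite
  huge lambda2 reproduces it to ~1e−4 and is tested as the limit.
* Grid-point kernel IRLS stops on linear-predictor stability (1e−7
  relative) or two consecutive objective increases (near-separation at
  vanishing penalties), capped at 30 iterations.

## Known limitations

* Only Gaussian and binomial families ship; no Cox/survival or
  multinomial, and no L1/elastic-net penalties at either level.
* One level of hierarchy: meta-features of meta-features are out of scope.
* Missing values are an error; no imputation.
* The exact closed form factors an n × n system, so extremely large n with
  p + q also large is better served by the coordinate-descent route.
* CV fold predictions for the binomial family rely on kernel IRLS without
  the full step-halving safeguard (the final refit always uses it); at
  penalties small enough for quasi-separation the CV loss surface can be
  noisy in a region CV will not select anyway.
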