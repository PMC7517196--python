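# Methods

## Model and synthetic posterior

`gammaboot` fits the normal-error linear model

    y_i = alpha + x_i' beta + eps_i,    eps_i ~ N(0, sigma2),

but replaces the log-likelihood in the posterior with the gamma-divergence
pseudo-likelihood

    R_gamma(theta) = (n/gamma) * log{ (1/n) sum_i
        ( f(y_i; alpha + x_i'beta, sigma2) / ||f||_{1+gamma} )^gamma },

where `||f||_{1+gamma} = {(2 pi sigma2)^(-gamma/2) (1+gamma)^(-1/2)}^{1/(1+gamma)}`
is the (1+gamma)-norm of the normal density.  The synthetic posterior is
`pi(theta) exp{R_gamma(theta)}`.  Because an observation enters only through
`f(y_i; .)^gamma`, a point with an extreme standardized residual contributes
essentially zero, so well-separated outliers are ignored rather than
accommodated; as `gamma -> 0` the standard posterior is recovered.  `gamma`
trades efficiency against robustness; the package default is `gamma = 0.2`,
a small value that already gives redescending behaviour while losing little
efficiency on clean data (data-driven selection of `gamma` is deliberately
out of scope).

## Posterior computation

Sampling uses the weighted-likelihood bootstrap: draw weights
`(w_1..w_n) ~ n * Dirichlet(1,...,1)` and minimize

    L_w(theta) = -(n/gamma) log{(1/n) sum_i w_i f(y_i;.)^gamma}
                 + beta' P beta / 2 + alpha^2/(2 S_alpha)
                 + (1 + a/2 - n gamma/(2(1+gamma))) log sigma2 + a/(2 sigma2),

whose minimizer is one approximate posterior draw (the approximation error
vanishes with n).  `P` is the coefficient prior precision and the sigma2
terms come from the inverse-gamma prior `IG(a/2, a/2)` on sigma2 — i.e.
`Ga(a/2, a/2)` on the precision, so `a = 2` encodes the common `Ga(1,1)`
choice.  The minimization is a Majorization-Minimization (MM) loop: Jensen's
inequality applied at the current point yields working weights

    s_i* = n w_i f(y_i;.)^gamma / sum_j w_j f(y_j;.)^gamma,

and a quadratic surrogate minimized in closed form (weighted ridge solve for
the coefficients; sigma2 update with divisor `2 + a + n/(1+gamma)`).  The
surrogate touches the objective at the current point, so the objective never
increases; the loop asserts this at every iteration.  Density powers are
computed in log space with max-subtraction, so extreme residuals underflow
to exact zeros instead of NaNs.

Convergence is declared when the relative objective change drops below
`mm_tol` (default 1e-8; cap `mm_max_iter = 1000` for standalone fits).
Standalone fits initialize from a lightly penalized ridge solve (penalty
1e-6) with the mean squared residual as the sigma2 start.

### Shrinkage priors and the outer Gibbs layer

For variable selection the coefficient prior is a scale mixture of normals,
`beta_k | u_k ~ N(0, u_k)` with

* Laplace (Bayesian lasso): `u_k | lambda^2 ~ Exp(lambda^2/2)`,
  `lambda^2 ~ Ga(c1, c2)`;
* horseshoe: `u_k | xi_k, lambda ~ IG(1/2, lambda/xi_k)`,
  `xi_k ~ IG(1/2, 1)`, `lambda ~ Ga(c1, c2)` — integrating `xi_k` out gives
  `p(u_k | lambda) proportional to u_k^{-1/2} (u_k + lambda)^{-1}`, the
  half-Cauchy mixing law (verified by quadrature in the tests).

One outer Gibbs scan draws fresh Dirichlet weights, runs the inner MM loop
(warm-started from the previous scan, iteration cap 2000) to obtain the
`(alpha, beta, sigma2)` draw, then refreshes the latent scales from their
conjugate full conditionals: for the Laplace prior
`1/u_k ~ inverse-Gaussian(mu = sqrt(lambda^2/beta_k^2), delta = lambda^2)`
(derived from the joint; the mean parameter uses `lambda^2`, not `lambda`)
and `lambda^2 ~ Ga(c1 + p, c2 + sum u_k / 2)`; for the horseshoe
`u_k ~ IG(1, lambda/xi_k + beta_k^2/2)`, `xi_k ~ IG(1, 1 + lambda/u_k)`,
`lambda ~ Ga(c1 + p/2, c2 + sum 1/(u_k xi_k))`.  Inverse-Gaussian draws use
the Michael-Schucany-Haas transformation.  Hyperprior defaults are
`c1 = c2 = 1`.

**Latent-update noise.**  The bootstrap minimizer is a point draw: in
directions where the prior dominates (strongly shrunk coordinates) it
suppresses exactly the conditional spread `beta_k^2 ~ u_k` that the scale
updates rely on.  Feeding the bare minimizer into the horseshoe conditionals
drives `(u, lambda)` into a degenerate absorbing collapse — `lambda`
underflows to zero and moderate signals are crushed — because the latent
conditionals are improper at `beta_k = 0` exactly, while the exact-conditional
Gibbs sampler (which draws `beta_k` with its conditional noise) is stable.
The latent updates therefore use a noised coefficient
`beta~_k ~ N(beta_k, v_k)`, with `v_k` the k-th diagonal of the inverse MM
surrogate curvature `(sum_i s_i x_i x_i'/sigma2 + P)^{-1}`.  In
prior-dominated directions `v_k ~ u_k`, restoring the missing spread; in
data-dominated directions `v_k ~ sigma2/n` and the perturbation is
negligible.  The reported `(alpha, beta, sigma2)` draws remain the
unmodified bootstrap minimizers.

Because each scan's coefficient draw starts from fresh, independent
Dirichlet weights, lag-1 autocorrelation of the coefficient draws is close
to zero (asserted below 0.2 in the tests), with no rejection step.

Non-convergence of an inner MM solve is flagged per draw, never silently
accepted; the replication driver excludes (with a logged count) any
replication carrying a flagged draw.

### Baselines

The non-robust comparison arms use the exact normal likelihood with
conjugate Gibbs updates: a normal/inverse-gamma sampler (with large prior
variances this is the flat-prior closed-form posterior) and a standard
Bayesian lasso (same Laplace latents, exact Gaussian full conditional for
the coefficients).

## Robustness diagnostics

* **Influence functions.**  For the simple model `y = alpha + beta x + eps`
  the Bayesian influence function of a posterior mean is
  `IF_k(z|x) = n Cov_post(theta_k, H(theta, z|x))`, where `H` is the
  contamination derivative of the (pseudo-)likelihood at contamination
  residual `z` and covariate point `x`, with the true conditional density
  `g(.|x) = N(x, 1)`.  Under the standard likelihood `H` is quadratic in `z`
  (unbounded influence); under the gamma-divergence `H` tends to `-1/gamma`
  as `|z|` grows, which makes the influence curves redescend to zero.  The
  inner integral over `g` uses 2000 Monte Carlo samples by default; the
  covariance runs over the posterior draws.
* **KL to the oracle.**  The oracle posterior is the normal-likelihood
  posterior fitted to the outlier-free subset.  The divergence
  `KL(pi* || pi)` over `(alpha, beta)` is estimated by moment-matching both
  draw sets to bivariate normals and applying the closed-form Gaussian KL:
  both posteriors are unimodal and near-Gaussian at n = 300, and the
  estimator is deterministic given the draws.  A k-NN estimator
  (`kl_knn`) is provided as a nonparametric cross-check; the two agree
  closely on this design.
* **Interval metrics.**  Point estimates are coordinatewise posterior
  medians; intervals are equal-tailed at the requested level (95% default).
  MSE, average length and coverage are averaged over coefficients, then over
  replications, with the Monte-Carlo standard error taken across
  replication means.

## Synthetic data

Two generators define the study conditions:

* **Simple-regression contamination** (`simple` design): n = 300,
  `alpha = 0, beta = 1, sigma2 = 1`, `x ~ N(0,1)`; the first
  `round(n omega)` errors are drawn from `N(0, a^2)` (deterministic
  placement, so the clean subset is identifiable for the oracle fit).
* **Sparse-regression contamination** (`scenario` design): n = 100, p = 20,
  `alpha = 0.5`, `beta = (0.5, 0, 0, 0.5, 0, 0, 2, 0, 0, 2, 0, 0, 2, 0...0)`,
  covariates `N_p(0, Sigma)` with `Sigma_ij = 0.2^|i-j|`; errors
  `(1 - omega_i) N(0,1) + omega_i f_c` with `f_c = N(0, 10^2)` (scenario I)
  or `N(10, 1)` (scenario II).  `omega_i` is constant (homogeneous) or
  `min(1, delta * logistic(-3.3 + x_{i,10}))` (heterogeneous; the standard
  logistic sigmoid, clipped at 1 because it is a probability).

The generators emulate vertical outliers in the response only; they do not
produce leverage points (contaminated covariates), missing data, or
non-normal clean errors, so passing tests demonstrate robustness to
response contamination, not to bad-leverage designs.

A noteworthy regime: with omega = 0.2 the Bernoulli contamination
occasionally yields replications with >30% outliers at n = 100, where the
gamma = 0.2 objective's global minimum is the non-robust large-sigma2 fit.
The warm-started sampler with healthy latent scales nonetheless remains in
the robust mode; this is a property of the warm-start dynamics, not of the
objective's global geometry.

## Desk-scale experiment sizes

The replication driver defaults to the full budgets (2000 kept draws after
1000 burn-in scans).  The packaged acceptance script uses reduced budgets
chosen as a deliberate compute/precision trade-off: 50 replications with
2000 kept draws for the KL experiment, and 100 replications with 500 kept /
250 burn-in scans for the coverage experiment.  At these sizes the
Monte-Carlo standard errors are ~0.01-0.05 nats (KL) and ~0.7-1.0
percentage points (coverage).

## Numerical choices and limitations

* Objective evaluations and working weights share one log-density pass per
  iteration; `logsumexp` guards underflow.  If every weighted density power
  underflows (all residuals astronomically large) a degenerate-weights error
  is raised rather than returning NaN.
* `|beta_k|` is floored at 1e-10 in the Laplace inverse-Gaussian update,
  whose mean parameter diverges at zero.
* The weighted ridge solve uses a Cholesky factorization; the SPD prior
  precision makes singularity impossible in exact arithmetic, and a
  numerical failure raises rather than silently continuing.
* Dirichlet weights are generated as normalized unit exponentials; weight
  vectors sum to n to within 1e-10 n.
* The gamma = 0 branch routes to exact formulas (normal log-likelihood,
  conjugate Gibbs) rather than evaluating the gamma expression at its
  removable singularity.
* The weighted bootstrap is an asymptotic approximation: for prior-dominated
  directions its draws are underdispersed (see the latent-noise paragraph),
  and for small n the posterior spread can be mildly miscalibrated.
* Bootstrap draws are exchangeable; permuting draw order leaves every
  summary unchanged.
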