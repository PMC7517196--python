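# gammaboot

Robust Bayesian linear regression via gamma-divergence synthetic posteriors,
with Bayesian-bootstrap-within-Gibbs sampling and shrinkage priors.

## The problem

Ordinary Bayesian linear regression is fragile: a handful of gross outliers
biases the coefficient posterior and inflates the error variance, and the
damage carries into credible intervals and variable selection.  `gammaboot`
targets analysts (e.g. in biostatistics and epidemiology) who want
fully Bayesian uncertainty quantification for `y = alpha + X beta + eps`
that keeps working when a fraction of responses is contaminated.

## The method

The log-likelihood in the posterior is replaced by the gamma-divergence
pseudo-likelihood

    R_gamma(beta, sigma2) = (n/gamma) log{ (1/n) sum_i
        ( f(y_i; x_i' beta, sigma2) / ||f||_{1+gamma} )^gamma },

which reduces to the log-likelihood as `gamma -> 0` and, for `gamma > 0`,
lets observations with extreme standardized residuals vanish from the fit
(`f^gamma -> 0`), yielding a synthetic posterior
`pi(theta) exp{R_gamma(theta)}` with *redescending* influence: a sufficiently
wild outlier has no effect at all, unlike heavy-tailed error models.

Posterior draws come from the weighted-likelihood bootstrap: each draw is the
minimizer of a Dirichlet-reweighted objective, computed by a
Majorization-Minimization loop with closed-form updates (monotone descent
guaranteed).  Laplace (Bayesian lasso) and horseshoe shrinkage priors are
supported through a Gibbs layer over their scale-mixture latents, so robust
estimation and Bayesian variable selection happen simultaneously.  There are
no Metropolis rejections and coefficient draws have near-zero
autocorrelation.  Non-robust conjugate baselines (normal/inverse-gamma Gibbs
and the standard Bayesian lasso) are included for comparison, along with
robustness diagnostics (Bayesian influence functions, KL divergence to a
clean-data oracle posterior) and a contaminated-data simulation harness.

## Worked example

Fit a robust Bayesian lasso to a CSV with 10% gross outliers (data generated
with `alpha = 1`, `beta = (2, -1, 0)`, `sigma2 = 1`, and 8 of 80 responses
shifted by +15):

```bash
gammaboot fit data.csv --response y --prior laplace --gamma 0.2 \
    --n-samples 1000 --n-burnin 500 --seed 1 --out-dir out_robust
```

```
parameter    median     lower     upper
    alpha  0.872058  0.685406  1.098298
       x1  2.030162  1.819686  2.248648
       x2 -0.998046 -1.241784 -0.778644
       x3 -0.046833 -0.244141  0.191125
   sigma2  0.797676  0.565346  1.117325
```

The posterior medians recover the generative values (the null coefficient
`x3` is shrunk to zero and its interval covers 0), and `sigma2` stays near 1:
the outliers were rejected, not absorbed.  The same command with
`--gamma 0` (the standard, non-robust Bayesian lasso) is wrecked by the same
8 points:

```
parameter    median     lower     upper
    alpha  2.321821  1.256052  3.444201
       x1  1.418762  0.393798  2.423776
       x2 -0.680002 -1.702224  0.203739
       x3 -0.344126 -1.492712  0.532709
   sigma2 22.780030 16.603663 31.997531
```

Each run writes `draws.csv` (one row per retained draw), `summary.csv`
(posterior medians and equal-tailed 95% intervals, shown above) and a
`manifest.json` recording the resolved configuration and seed, so reruns are
bit-for-bit reproducible.  `gammaboot simulate experiment.yaml --out-dir ...`
drives replicated contamination experiments from a YAML description; the
library API (`bootstrap_posterior`, `gibbs_shrinkage`, `baseline_gibbs`,
`influence_function`, `kl_to_oracle`, `run_replications`, ...) exposes the
same functionality programmatically.  See `docs/methods.md` for the model,
algorithm and design details.

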