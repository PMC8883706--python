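# Methods

## Model

For a two-arm trial with continuous outcome `y_i`, treatment indicator
`t_i` and covariates `x_i`, the package fits

    y_i ~ D(mu_i, sigma_i, nu_i, tau_i)   independently,

with a link-linear predictor per distribution parameter,

    g_k(theta_i) = b0 + bt*t_i + b1*x_i1 + ...    (theta in {mu, sigma, nu, tau}).

Links are identity or log; defaults per family are the conventional ones
(identity for real-valued location/shape parameters, log for strictly
positive scale/kurtosis parameters, log for the positive-support BCT
median). Terms are the intercept, any dataset column, or `log(column)`.
Only linear terms are supported: smooth/spline and spatial effects are out
of scope, as is Bayesian estimation and GEE-style marginal modelling.

### Families

* **Normal (`NO`)** — mean `mu`, SD `sigma`.
* **Johnson S_u (`JSU`)** — implemented in the mean/SD form: with
  `Z ~ N(0,1)`, `y = mu + A + B*sinh((Z + nu)/tau)`, where `B = c*sigma`
  and the offset `A` and constant `c` are the moment-matching functions of
  `(sigma, nu, tau)` that make `E[y] = mu` and `SD[y] = sigma` *exactly*
  (verified by quadrature in the tests to 1e-6). `nu = 0` gives symmetry;
  `tau → ∞` approaches the normal.
* **Box-Cox t (`BCT`)** — for `y > 0`, the Box-Cox power transform
  `z = ((y/mu)^nu − 1)/(sigma*nu)` (`z = log(y/mu)/sigma` at `nu = 0`)
  follows a t distribution with `tau` degrees of freedom truncated to the
  admissible range, with normalizing constant `F_T(1/(sigma*|nu|); tau)`.
  `mu` is the approximate median (the package reports the exact numeric
  `quantile(0.5)` where a median is needed), `sigma` the approximate
  coefficient of variation.
* **Skew normal (`SN`)** — the Azzalini three-parameter form
  `f(y) = (2/sigma) φ(z) Φ(nu*z)`, `z = (y−mu)/sigma`. The Azzalini
  variant was chosen because it is the standard location–scale–shape skew
  normal; a two-piece variant would change none of the package's
  interfaces.

Densities are computed on the log scale throughout (`gammaln`,
`log_ndtr`, `log1p`), CDFs and quantiles through `scipy.special`
primitives (`stdtr`/`stdtrit`, `ndtr`/`ndtri`, `owens_t`); the skew-normal
quantile uses the scipy implementation. All families satisfy, on an
admissible parameter grid: density integrates to 1 (quadrature, 1e-6),
`quantile(cdf(y)) = y` (1e-8), pdf equals the central-difference
derivative of the CDF (1e-5), and samplers pass a Kolmogorov–Smirnov test
against their own CDF.

### Left-censoring at a detection limit

A `CensoredFamily` wraps any base family with a cutoff interior to its
support (only left censoring is implemented; the motivating use is an
assay detection limit such as 0.05 nmol/L). Censored records contribute
`log F(cutoff | params_i)` to the likelihood, uncensored records
`log f(y_i | params_i)`; with no censored records the censored and
uncensored log-likelihoods agree exactly. Quantiles and random generation
are defined on the base family — censoring is a property of the
observation process, not the latent distribution.

## Estimation

All coefficient blocks are maximized jointly: the packed coefficient
vector is optimized by BFGS (finite-difference gradients) on the negative
log-likelihood, followed by a Newton polish using a central-difference
gradient and numeric Hessian. This replaces the backfitting (RS) algorithm
of classical GAMLSS software with a single joint optimization — same
optimum, easier to verify against closed-form oracles (the homoscedastic
normal fit reproduces least squares to 1e-6).

* **Starting values**: the `mu` block from least squares on the
  (link-transformed) response; the `sigma` intercept from the residual
  spread; `nu` at 0 (0.5 for BCT); `tau` at 5 (BCT) or 2 (JSU) on the log
  scale. These are conventional mild defaults.
* **Inadmissible coefficients** (e.g. `sigma ≤ 0` under an identity link,
  or guard violations `sigma ∉ (1e-10, 1e10)`, `tau < 0.05`) give a
  flagged `-inf` log-likelihood inside the optimizer, never an exception.
* **Convergence** is declared when the central-difference gradient
  satisfies `max|grad| < 1e-5 · max(1, |loglik|)`; the relative form is
  used because the attainable absolute gradient scales with the
  log-likelihood magnitude under finite-difference arithmetic. Failed
  BFGS runs are restarted once from the best point; non-convergence is
  reported on the results object, never raised.
* **Standard errors** come from the inverse observed information (central
  numeric Hessian, symmetrized). A singular or indefinite information
  matrix yields NaN SEs with a warning.
* **df and AIC**: every estimated scalar counts 1 (including the
  random-intercept SD); `AIC = −2·loglik + 2·df` exactly.
* The `sigma` predictor models **log sigma**, not log sigma². A
  coefficient `b` on log sigma equals `2b` on log sigma²; `exp(b)` is the
  multiplicative effect on the SD.

### Random intercept

A Gaussian subject intercept on the `mu` predictor (only `mu`) is
integrated out by adaptive Gauss–Hermite quadrature: per subject the
integrand is recentred at its mode — found by a vectorized Newton
iteration with numeric derivatives — and rescaled by the mode curvature
before applying the quadrature rule (15 nodes by default; exact for the
Gaussian case, where the fit matches statsmodels MixedLM maximum
likelihood to better than 1e-4). Random-intercept fits are warm-started
from the fixed-effects fit, with the residual variance split into
between/within-subject parts to initialize the intercept SD; the marginal
likelihood uses central-difference gradients because forward differences
are too noisy for a quadrature-valued objective. The SD is estimated on
the log scale and reported on the natural scale with a delta-method SE.
With all subjects singleton the SD is weakly identified; the fit proceeds
with a warning. At a true SD of zero the estimate collapses toward the
boundary (small relative to the residual scale) rather than to an exact
zero — a known boundary property of maximum likelihood.

## Diagnostics and inference

* **Normalized quantile residuals**: `r_i = ndtri(F(y_i | fitted
  params_i))`; censored records draw `u_i ~ Uniform(0, F(cutoff))` with a
  fixed seed and use `ndtri(u_i)`, so they are reproducible, never exceed
  the probit of the fitted censoring probability, and two seeds differ
  only at censored records. Residuals are clamped at ±8.2 (with a
  warning) where the CDF saturates in double precision. QQ output is a
  plain coordinate table (theoretical vs empirical quantiles); no
  plotting dependency.
* **Wald tests** use the standard-normal reference (z values), matching
  maximum-likelihood software convention; no t correction and no
  multiple-testing adjustment.
* **LR test** for the joint no-treatment-effect hypothesis on `mu` and
  `sigma` uses chi-square with 2 df; a negative statistic beyond a small
  tolerance raises (it signals an optimizer failure in one of the fits).
* **Selection** fits each candidate family under a shared template —
  treatment on the mean only for the normal, on `mu` and `sigma` for the
  others (configurable) — and ranks by AIC. Candidates whose support
  excludes an observed response are skipped with a logged reason;
  non-converged candidates are excluded; if none converge an error
  carrying per-candidate diagnostics is raised.

## Synthetic-trial generator

The real trial data are not available, so the generator defines the study
conditions used everywhere:

* treatment ~ Bernoulli(0.5), independent of baseline (the original study
  reused real allocations, which cannot be reproduced);
* baseline biomarker ~ log-normal(log 0.65, 0.25) — an invented,
  configurable stand-in for an MR-proADM-like marker with median
  0.65 nmol/L; blood-pressure scenarios use a truncated normal(140, 18);
* sex ~ Bernoulli(0.8) (the trial population was predominantly male);
* response drawn from the configured family with row-wise parameters
  through the links, using the shipped coefficient sets (the published
  fitted models for the biomarker and blood-pressure outcomes, including
  the longitudinal set with subject-intercept SD 10.712);
* censoring applied last: responses at/below the cutoff (0.05 for the
  biomarker scenario) are stored at the cutoff with a 0/1 flag, as
  detection-limit data are entered in practice.

What the generator does **not** emulate: the empirical baseline
distribution of the original 6,539 participants (so power- and
coverage-type quantities can differ from the published ones by the
influence of that covariate distribution), survival endpoints, dropout
and visit missingness. Passing tests therefore demonstrate correctness of
the methods under these stated conditions, not agreement with the
original data.

## Monte-Carlo studies and problem sizes

Replicate seeds are spawned from a master seed via
`numpy.random.SeedSequence`, making studies reproducible and independent
of execution order; failed replicates are excluded from aggregates and
counted. Default sizes: the coverage study runs 500 replicates at
n = 2000 (the acceptance script's `t1`), the selection study 100
replicates at n = 2000 (`t2`). The test suite uses smaller replicate
counts for the recovery and size/power checks (20–200 replicates at
n = 1000–5000, stated per test) — sizes chosen so Monte-Carlo error is
small against the tested tolerances. Alpha is fixed at 0.05 and intervals
at 95% throughout, both configurable.

## Known limitations

* Only identity and log links; no probit/inverse links.
* Only left censoring; no right or interval censoring.
* Random intercepts only on `mu`, one grouping level, Gaussian.
* BCT fits with very heavy tails (`tau` near the 0.05 guard) can be
  slow to converge; the guard bounds are numeric, not statistical.
* The Wald/LR inference is asymptotic; no small-sample or bootstrap
  corrections.
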