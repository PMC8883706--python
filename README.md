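# distreg

Distributional (location–scale–shape) regression for two-arm clinical
trials with continuous outcomes.

Classical trial analysis fits a normal linear model and estimates a
treatment effect on the mean. When the outcome is skewed, heavy-tailed,
heteroscedastic, or censored at an assay detection limit, that model is
misspecified — and it cannot see treatment effects on anything but the
mean. `distreg` fits models of the form

```
y_i ~ D(mu_i, sigma_i, nu_i, tau_i)        independently
g_1(mu_i)    = b0_mu    + bt_mu t_i    + b1_mu x_i1   + ...
g_2(sigma_i) = b0_sigma + bt_sigma t_i + b1_sigma x_i1 + ...
g_3(nu_i)    = ...
g_4(tau_i)   = ...
```

where `t_i` is the 0/1 treatment indicator, every distribution parameter
gets its own link-linear predictor, and `D` is one of

* `NO` — normal (mean `mu`, SD `sigma`),
* `JSU` — Johnson's S_u, parameterized so `mu` is the mean and `sigma`
  the SD, with skewness `nu` and kurtosis `tau`,
* `BCT` — Box-Cox t on (0, ∞): `mu` ≈ median, `sigma` ≈ coefficient of
  variation, `nu` skewness, `tau` kurtosis (t degrees of freedom),
* `SN` — Azzalini skew normal.

Any family can be left-censored at a detection limit (censored records
contribute the CDF at the cutoff to the likelihood), and a Gaussian
random intercept on the `mu` predictor handles longitudinal data.
Estimation is joint maximum likelihood; standard errors come from the
inverse observed information. Diagnostics include normalized (randomized)
quantile residuals, Wald and likelihood-ratio treatment-effect tests,
multiplicative effect displays `exp(beta)` for log-linked parameters, and
AIC-based selection among candidate families. A synthetic-trial generator
and a Monte-Carlo harness reproduce coverage, selection and power studies.

## Worked example

```python
import numpy as np
from distreg import (GeneratorConfig, ModelSpec, DistributionalModel,
                     gen_trial, select_distribution, quantile_residuals)

# a biomarker-like trial: positively skewed response, log-normal baseline,
# detection limit 0.05; generated from the shipped Box-Cox-t coefficients
cfg = GeneratorConfig.from_coefset("mrproadm_extended_bct", n=2000,
                                   censor_cutoff=0.05)
data = gen_trial(cfg, seed=3)

spec = ModelSpec(family="BCT",
                 mu=("treatment", "log(baseline)"),
                 sigma=("treatment", "log(baseline)"),
                 censor_cutoff=0.05)
res = DistributionalModel(data, spec).fit()
print(res.summary())
```

prints

```
Distributional regression fit
================================================================
Family: BCT left-censored at 0.05    n = 2000    censored = 2
log-likelihood = 1451.248   df = 8   AIC = -2886.496   converged = True
----------------------------------------------------------------
coefficient                   estimate        SE       z       p
mu.(Intercept)                  -0.104     0.005  -20.59   0.000
mu.treatment                    -0.016     0.006   -2.96   0.003
mu.log(baseline)                 0.891     0.011   77.71   0.000
sigma.(Intercept)               -2.766     0.074  -37.38   0.000
sigma.treatment                 -0.006     0.061   -0.10   0.919
sigma.log(baseline)             -1.064     0.127   -8.37   0.000
nu.(Intercept)                   1.774     0.308    5.76   0.000
tau.(Intercept)                  0.261     0.074    3.50   0.000
================================================================
```

`mu.treatment = -0.016` is the treatment effect on the log of the
(approximate) median: the treated arm's median biomarker is
`exp(-0.016) = 0.984` times the control arm's, a significant ~1.6%
reduction (p = 0.003). `sigma.treatment` would be a multiplicative
treatment effect on the coefficient of variation. The AIC column of

```python
sel = select_distribution(data, ("NO", "JSU", "BCT", "SN"),
                          ModelSpec(mu=("treatment", "log(baseline)"),
                                    sigma=("treatment", "log(baseline)")))
print(sel.ranking)
# [('BCT', -2900.94), ('JSU', -2724.23), ('SN', -1240.54), ('NO', 518.20)]
```

shows the Box-Cox t beating the normal by over 3400 AIC points on this
skewed outcome, and `quantile_residuals(res, seed=17)` gives residuals
that are standard normal when the model is right.

The command-line interface exposes the same pipeline as `distreg fit`,
`distreg diagnose`, `distreg select`, `distreg simulate-data` and
`distreg replicate`.

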