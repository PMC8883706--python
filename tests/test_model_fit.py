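"""Maximum-likelihood fitting: oracle equivalences and recovery checks.

The homoscedastic-normal fit is checked against the closed-form
least-squares solution; the Gaussian random-intercept fit against
statsmodels MixedLM (an independent maximum-likelihood implementation);
parameter recovery against the generating coefficients of synthetic trials.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from distreg import (DistributionalModel, GeneratorConfig, ModelSpec,
                     TrialDataset, fit_ml, fit_random_intercept, gen_trial,
                     loglik)


def test_normal_ml_equals_least_squares(normal_trial):
    """Homoscedastic normal ML reproduces OLS coefficients and classical SEs
    (after the ML -> unbiased variance correction sqrt(n/(n-p)))."""
    spec = ModelSpec(family="NO", mu=("treatment", "log(baseline)"))
    res = fit_ml(normal_trial, spec)
    X = sm.add_constant(np.column_stack([
        normal_trial.treatment, np.log(normal_trial.df["baseline"])]))
    ols = sm.OLS(normal_trial.response, X).fit()
    assert res.params.iloc[:3].to_numpy() == pytest.approx(
        ols.params, abs=1e-6)
    n, p = normal_trial.n, 3
    corrected = res.bse.iloc[:3].to_numpy() * np.sqrt(n / (n - p))
    assert corrected == pytest.approx(ols.bse, abs=1e-6)
    assert res.converged


def test_loglik_closed_form():
    df = pd.DataFrame({"response": [1.0, 2.0, 3.0], "treatment": [0, 1, 0]})
    spec = ModelSpec(family="NO", mu=(), sigma=())  # intercept-only
    # theta = [mu intercept, log sigma intercept]
    val = loglik(df, spec, np.array([2.0, 0.0]))
    assert val == pytest.approx(-1.5 * np.log(2 * np.pi) - 1.0, abs=1e-10)


def test_loglik_inadmissible_coefficients_flagged_not_raised():
    df = pd.DataFrame({"response": [1.0, 2.0, 3.0], "treatment": [0, 1, 0]})
    spec = ModelSpec(family="NO", links={"sigma": "identity"})
    val = loglik(df, spec, np.array([2.0, -1.0]))  # sigma = -1
    assert val == -np.inf


def test_loglik_is_local_maximum(normal_trial):
    spec = ModelSpec(family="NO", mu=("treatment", "log(baseline)"))
    model = DistributionalModel(normal_trial, spec)
    res = model.fit()
    rng = np.random.default_rng(5)
    for _ in range(20):
        perturbed = res.theta + rng.normal(0, 0.02, len(res.theta))
        assert model.loglik(perturbed) <= res.llf + 1e-8


def test_censored_fit_identical_without_censored_records(normal_trial):
    spec = ModelSpec(family="NO", mu=("treatment",))
    spec_c = ModelSpec(family="NO", mu=("treatment",),
                       censor_cutoff=float(normal_trial.response.min()) - 1.0)
    res = fit_ml(normal_trial, spec)
    res_c = fit_ml(normal_trial, spec_c)
    assert res_c.llf == pytest.approx(res.llf, abs=1e-10)
    assert res_c.theta == pytest.approx(res.theta, abs=1e-10)


def test_nested_spec_never_decreases_loglik(normal_trial):
    reduced = fit_ml(normal_trial, ModelSpec(family="NO", mu=("treatment",)))
    extended = fit_ml(normal_trial, ModelSpec(
        family="NO", mu=("treatment", "log(baseline)")))
    assert extended.llf >= reduced.llf - 1e-8


def test_aic_identity_and_ordering(normal_trial):
    res = fit_ml(normal_trial, ModelSpec(family="NO", mu=("treatment",)))
    assert res.aic == -2.0 * res.llf + 2.0 * res.df
    assert res.df == 3


def test_covariance_symmetric_psd_and_gradient_small(normal_trial):
    spec = ModelSpec(family="NO", mu=("treatment", "log(baseline)"))
    res = fit_ml(normal_trial, spec)
    C = res.cov_params().to_numpy()
    assert np.allclose(C, C.T, atol=1e-12)
    assert np.linalg.eigvalsh(C).min() > -1e-10
    grad = res.score_at_optimum()
    assert np.max(np.abs(grad)) < 1e-5 * max(1.0, abs(res.llf))


def test_covariate_rescaling_invariance(normal_trial):
    """Scaling a covariate by c divides its coefficient by c and leaves the
    log-likelihood unchanged (checked as an exact reparameterization)."""
    df2 = normal_trial.df.copy()
    df2["scaled"] = 2.0 * np.log(df2["baseline"])
    spec1 = ModelSpec(family="JSU", mu=("treatment", "log(baseline)"))
    spec2 = ModelSpec(family="JSU", mu=("treatment", "scaled"))
    m1 = DistributionalModel(TrialDataset(df2), spec1)
    m2 = DistributionalModel(TrialDataset(df2), spec2)
    r1 = m1.fit()
    theta_mapped = r1.theta.copy()
    theta_mapped[2] /= 2.0  # coefficient of the scaled covariate
    assert m2.loglik(theta_mapped) == pytest.approx(r1.llf, abs=1e-8)
    r2 = m2.fit()
    assert r2.params["mu.scaled"] == pytest.approx(
        r1.params["mu.log(baseline)"] / 2.0, rel=1e-4)
    assert r2.llf == pytest.approx(r1.llf, abs=1e-6)


def test_jsu_coefficient_recovery_single_trial():
    cfg = GeneratorConfig.from_coefset("sbp_extended_jsu", n=5000,
                                       sex_prevalence=None)
    data = gen_trial(cfg, seed=31)
    spec = ModelSpec(family="JSU", mu=("treatment", "baseline"),
                     sigma=("treatment", "baseline"), nu=("baseline",))
    res = fit_ml(data, spec)
    assert res.converged
    truth = {"mu.(Intercept)": 79.722, "mu.treatment": 0.042,
             "mu.baseline": -0.589, "sigma.(Intercept)": 2.473,
             "sigma.treatment": -0.067, "sigma.baseline": 0.003,
             "nu.(Intercept)": 4.018, "nu.baseline": -0.018,
             "tau.(Intercept)": 1.160}
    z = (res.params[list(truth)] - pd.Series(truth)) / res.bse[list(truth)]
    assert np.abs(z.to_numpy()).max() < 4.0


def test_random_intercept_matches_mixedlm_oracle():
    rng = np.random.default_rng(5)
    n_subj = 300
    b = rng.normal(0, 2.0, n_subj)
    rows = []
    for j in range(n_subj):
        for _ in range(2):
            x = rng.normal()
            t = j % 2
            rows.append(dict(id=j, treatment=t, x=x,
                             response=1.0 + 0.5 * t + 0.8 * x + b[j]
                             + rng.normal(0, 1.0)))
    df = pd.DataFrame(rows)
    spec = ModelSpec(family="NO", mu=("treatment", "x"),
                     random_intercept="id")
    res = fit_random_intercept(df, spec)
    ref = smf.mixedlm("response ~ treatment + x", df,
                      groups=df["id"]).fit(reml=False)
    ours = res.params[["mu.(Intercept)", "mu.treatment", "mu.x"]].to_numpy()
    assert ours == pytest.approx(ref.fe_params.to_numpy(), rel=1e-4)
    assert res.random_effect_sd == pytest.approx(
        np.sqrt(ref.cov_re.values[0, 0]), rel=1e-4)
    assert res.llf == pytest.approx(ref.llf, abs=1e-4)


def test_random_intercept_sd_near_zero_boundary():
    """With no true subject effect the estimated SD collapses toward the
    boundary (small relative to the residual scale)."""
    rng = np.random.default_rng(8)
    n_subj = 250
    rows = []
    for j in range(n_subj):
        for _ in range(2):
            rows.append(dict(id=j, treatment=j % 2,
                             response=1.0 + rng.normal(0, 1.0)))
    df = pd.DataFrame(rows)
    spec = ModelSpec(family="NO", mu=("treatment",), random_intercept="id")
    res = fit_random_intercept(df, spec)
    assert res.random_effect_sd < 0.5  # residual SD is 1


def test_n_obs_must_exceed_coefficient_count():
    df = pd.DataFrame({"response": [1.0, 2.0], "treatment": [0, 1]})
    with pytest.raises(ValueError, match="n_obs"):
        DistributionalModel(df, ModelSpec(family="NO", mu=("treatment",)))


def test_summary_mentions_fit_statistics(normal_trial):
    res = fit_ml(normal_trial, ModelSpec(family="NO", mu=("treatment",)))
    text = res.summary()
    assert "AIC" in text and "mu.treatment" in text
    assert f"n = {normal_trial.n}" in text
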