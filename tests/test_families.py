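"""Distributional contracts of the response families.

Independent oracles: adaptive quadrature for normalization and moments,
bracketed root-finding on the CDF for quantiles, central differences for
the pdf/CDF consistency, and Kolmogorov-Smirnov tests for samplers.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq

from distreg import censor_left, get_family
from distreg.families import ParameterError, SupportError

# one admissible parameter grid per family, spanning symmetric/skewed and
# light/heavy-tailed corners
PARAM_GRID = [
    ("NO", dict(mu=0.0, sigma=1.0)),
    ("NO", dict(mu=-3.0, sigma=0.4)),
    ("JSU", dict(mu=5.0, sigma=2.0, nu=1.0, tau=3.0)),
    ("JSU", dict(mu=0.0, sigma=1.0, nu=0.0, tau=2.0)),
    ("JSU", dict(mu=-2.0, sigma=0.5, nu=-1.5, tau=5.0)),
    ("BCT", dict(mu=1.0, sigma=0.2, nu=1.0, tau=10.0)),
    ("BCT", dict(mu=0.6, sigma=0.1, nu=-0.5, tau=2.0)),
    ("BCT", dict(mu=1.0, sigma=0.3, nu=0.0, tau=5.0)),
    ("BCT", dict(mu=2.0, sigma=0.15, nu=2.0, tau=4.0)),
    ("SN", dict(mu=1.0, sigma=2.0, nu=3.0)),
    ("SN", dict(mu=0.0, sigma=1.0, nu=-2.0)),
]

IDS = [f"{n}-{i}" for i, (n, _) in enumerate(PARAM_GRID)]


def _interior_points(fam, params):
    qs = np.array([0.01, 0.1, 0.35, 0.5, 0.65, 0.9, 0.99])
    return np.asarray(fam.ppf(qs, **params))


@pytest.mark.parametrize("name,params", PARAM_GRID, ids=IDS)
def test_density_normalizes(name, params):
    fam = get_family(name)
    lo, hi = fam.support
    total, _ = quad(lambda y: fam.pdf(y, **params), lo, hi, limit=400)
    assert total == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("name,params", PARAM_GRID, ids=IDS)
def test_cdf_monotone_with_correct_limits(name, params):
    fam = get_family(name)
    y = _interior_points(fam, params)
    F = np.asarray(fam.cdf(y, **params))
    assert np.all(np.diff(F) > 0)
    assert np.all((F >= 0) & (F <= 1))
    assert fam.cdf(fam.ppf(1e-12, **params), **params) < 1e-10
    assert fam.cdf(fam.ppf(1 - 1e-12, **params), **params) > 1 - 1e-10


@pytest.mark.parametrize("name,params", PARAM_GRID, ids=IDS)
def test_quantile_cdf_identity(name, params):
    fam = get_family(name)
    y = _interior_points(fam, params)
    back = np.asarray(fam.ppf(fam.cdf(y, **params), **params))
    assert back == pytest.approx(y, rel=1e-8, abs=1e-8)


@pytest.mark.parametrize("name,params", PARAM_GRID, ids=IDS)
def test_pdf_is_cdf_derivative(name, params):
    fam = get_family(name)
    y = _interior_points(fam, params)[1:-1]
    h = 1e-5 * np.maximum(1.0, np.abs(y))
    deriv = (np.asarray(fam.cdf(y + h, **params))
             - np.asarray(fam.cdf(y - h, **params))) / (2 * h)
    assert deriv == pytest.approx(np.asarray(fam.pdf(y, **params)), rel=2e-5,
                                  abs=1e-7)


@pytest.mark.parametrize("name,params", PARAM_GRID, ids=IDS)
def test_sampler_matches_cdf_and_is_reproducible(name, params):
    fam = get_family(name)
    draws = fam.rvs(size=4000, random_state=7, **params)
    p = stats.kstest(draws, lambda y: np.asarray(fam.cdf(y, **params))).pvalue
    assert p > 1e-3
    assert np.array_equal(draws, fam.rvs(size=4000, random_state=7, **params))


def test_normal_closed_forms():
    no = get_family("NO")
    assert no.pdf(0.0, mu=0.0, sigma=1.0) == pytest.approx(
        1.0 / np.sqrt(2 * np.pi), abs=1e-7)
    assert no.cdf(2.0, mu=2.0, sigma=3.0) == pytest.approx(0.5, abs=1e-12)
    assert no.ppf(0.5, mu=3.0, sigma=2.0) == pytest.approx(3.0, abs=1e-12)


def test_jsu_symmetric_when_nu_zero():
    jsu = get_family("JSU")
    p = dict(mu=2.0, sigma=1.0, nu=0.0, tau=2.0)
    d = np.linspace(0.1, 2.5, 7)
    assert np.asarray(jsu.pdf(2.0 + d, **p)) == pytest.approx(
        np.asarray(jsu.pdf(2.0 - d, **p)), rel=1e-10)
    assert jsu.cdf(2.0, **p) == pytest.approx(0.5, abs=1e-12)
    hi, lo = jsu.ppf(0.975, **p), jsu.ppf(0.025, **p)
    assert hi - 2.0 == pytest.approx(2.0 - lo, rel=1e-9)


def test_jsu_mean_sd_parameterization_by_quadrature():
    """mu and sigma are the exact mean and SD (quadrature-moment oracle)."""
    jsu = get_family("JSU")
    for p in [dict(mu=5.0, sigma=2.0, nu=1.0, tau=3.0),
              dict(mu=-2.0, sigma=0.5, nu=-1.5, tau=5.0),
              dict(mu=0.0, sigma=1.0, nu=0.5, tau=2.0)]:
        mean, _ = quad(lambda y: y * jsu.pdf(y, **p), -np.inf, np.inf,
                       limit=400)
        var, _ = quad(lambda y: (y - p["mu"]) ** 2 * jsu.pdf(y, **p),
                      -np.inf, np.inf, limit=400)
        assert mean == pytest.approx(p["mu"], abs=1e-6)
        assert np.sqrt(var) == pytest.approx(p["sigma"], abs=1e-6)


def test_jsu_sample_moments():
    jsu = get_family("JSU")
    draws = jsu.rvs(size=10**6, random_state=3, mu=5.0, sigma=2.0, nu=1.0,
                    tau=3.0)
    mc_se = 2.0 / 1000.0  # sigma / sqrt(n)
    assert abs(draws.mean() - 5.0) < 4 * mc_se
    assert abs(draws.std() - 2.0) < 8 * mc_se  # SD of the SD is larger


def test_bct_median_matches_bisection_oracle():
    bct = get_family("BCT")
    p = dict(mu=1.0, sigma=0.2, nu=1.0, tau=10.0)
    med = brentq(lambda y: float(bct.cdf(y, **p)) - 0.5, 0.5, 2.0,
                 xtol=1e-12)
    assert float(bct.ppf(0.5, **p)) == pytest.approx(med, abs=1e-10)
    # mu is the approximate median
    assert med == pytest.approx(1.0, rel=1e-3)
    assert float(bct.cdf(bct.ppf(0.5, **p), **p)) == pytest.approx(0.5,
                                                                   abs=1e-12)


def test_bct_support_is_positive():
    bct = get_family("BCT")
    draws = bct.rvs(size=20000, random_state=11, mu=0.6, sigma=0.4, nu=-0.5,
                    tau=3.0)
    assert np.all(draws > 0)
    with pytest.raises(SupportError):
        bct.pdf(-1.0, mu=1.0, sigma=0.2, nu=1.0, tau=5.0)


def test_bct_nu_zero_is_log_t():
    """At nu=0 the log of a BCT draw is scaled t (KS oracle)."""
    bct = get_family("BCT")
    draws = bct.rvs(size=200000, random_state=9, mu=1.0, sigma=0.3, nu=0.0,
                    tau=5.0)
    z = np.log(draws) / 0.3
    assert stats.kstest(z, stats.t(5).cdf).pvalue > 0.01


def test_inadmissible_parameters_name_the_offender():
    with pytest.raises(ParameterError, match="sigma"):
        get_family("NO").pdf(0.0, mu=0.0, sigma=-1.0)
    with pytest.raises(ParameterError, match="tau"):
        get_family("JSU").pdf(0.0, mu=0.0, sigma=1.0, nu=0.0, tau=-2.0)
    with pytest.raises(ParameterError, match="mu"):
        get_family("BCT").pdf(1.0, mu=-1.0, sigma=0.2, nu=1.0, tau=5.0)


def test_quantile_level_domain_error():
    with pytest.raises(ValueError):
        get_family("NO").ppf(1.5, mu=0.0, sigma=1.0)
    with pytest.raises(ValueError):
        get_family("NO").ppf(0.0, mu=0.0, sigma=1.0)


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------

def test_censored_contribution_is_base_cdf_at_cutoff():
    cens = censor_left("NO", 0.0)
    ll = cens.loglik_terms(np.array([0.0]), np.array([1]), mu=0.0, sigma=1.0)
    assert ll[0] == pytest.approx(np.log(0.5), abs=1e-12)


def test_censored_loglik_equals_uncensored_without_censored_records():
    bct = get_family("BCT")
    cens = censor_left(bct, 0.05)
    y = bct.rvs(size=500, random_state=2, mu=0.6, sigma=0.2, nu=0.5, tau=5.0)
    assert np.all(y > 0.05)
    params = dict(mu=0.6, sigma=0.2, nu=0.5, tau=5.0)
    lc = cens.loglik_terms(y, np.zeros(len(y)), **params)
    lu = bct.logpdf(y, **params)
    assert np.array_equal(lc, lu)


def test_censoring_probability_conservation():
    """P(censored) + integral of the density above the cutoff = 1."""
    bct = get_family("BCT")
    params = dict(mu=0.6, sigma=0.3, nu=0.5, tau=5.0)
    cutoff = 0.3
    p_cens = float(bct.cdf(cutoff, **params))
    upper, _ = quad(lambda y: bct.pdf(y, **params), cutoff, np.inf, limit=400)
    assert p_cens + upper == pytest.approx(1.0, abs=1e-6)


def test_censored_fraction_matches_cdf():
    bct = get_family("BCT")
    params = dict(mu=0.6, sigma=0.3, nu=0.5, tau=5.0)
    cutoff = 0.3
    p = float(bct.cdf(cutoff, **params))
    draws = bct.rvs(size=50000, random_state=4, **params)
    frac = np.mean(draws <= cutoff)
    mc_se = np.sqrt(p * (1 - p) / 50000)
    assert abs(frac - p) < 4 * mc_se


def test_cutoff_outside_support_rejected():
    with pytest.raises(SupportError):
        censor_left("BCT", -0.1)


# ---------------------------------------------------------------------------
# property-based round trip over random admissible parameters
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    mu=st.floats(-5, 5),
    sigma=st.floats(0.2, 3.0),
    nu=st.floats(-2.0, 2.0),
    tau=st.floats(1.0, 10.0),
    q=st.floats(0.01, 0.99),
)
def test_jsu_roundtrip_property(mu, sigma, nu, tau, q):
    jsu = get_family("JSU")
    y = float(jsu.ppf(q, mu=mu, sigma=sigma, nu=nu, tau=tau))
    assert float(jsu.cdf(y, mu=mu, sigma=sigma, nu=nu, tau=tau)) == \
        pytest.approx(q, abs=1e-8)
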