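"""Parametric response families for distributional regression.

Each family has up to four parameters, conventionally named

* ``mu``    — location (mean, or approximate median for positive families),
* ``sigma`` — scale (standard deviation, or approximate coefficient of
  variation for the Box-Cox-t),
* ``nu``    — skewness,
* ``tau``   — kurtosis,

and exposes vectorized ``logpdf`` / ``pdf`` / ``cdf`` / ``logcdf`` / ``ppf`` /
``rvs``.  The registry maps the short names used throughout ("NO", "JSU",
"BCT", "SN") to singleton instances.  ``censor_left`` wraps any family with a
left-censoring cutoff (a biomarker detection limit): censored records
contribute the CDF at the cutoff to the likelihood instead of the density.

Families implemented:

``NO``
    Normal with mean ``mu`` and standard deviation ``sigma``.
``JSU``
    Johnson's S_u in the mean/SD parameterization: a moment-matching affine
    transform of Johnson's original sinh system such that ``mu`` is exactly
    the mean and ``sigma`` exactly the standard deviation; ``nu`` controls
    skewness (0 = symmetric) and ``tau > 0`` kurtosis (large tau -> normal).
``BCT``
    Box-Cox t on (0, inf): the Box-Cox power transform
    ``z = ((y/mu)**nu - 1) / (sigma*nu)`` (``z = log(y/mu)/sigma`` at nu=0)
    is modelled as a truncated t with ``tau`` degrees of freedom, with the
    truncation-normalizing constant ``F_T(1/(sigma*|nu|))``.  ``mu`` is the
    approximate median, ``sigma`` the approximate coefficient of variation.
``SN``
    Azzalini's skew normal with location ``mu``, scale ``sigma`` and shape
    ``nu`` (nu=0 reduces to the normal).
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "Family",
    "NormalFamily",
    "JSUFamily",
    "BCTFamily",
    "SkewNormalFamily",
    "CensoredFamily",
    "censor_left",
    "get_family",
    "FAMILY_REGISTRY",
    "ParameterError",
    "SupportError",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


class ParameterError(ValueError):
    """An inadmissible distribution parameter was supplied."""


class SupportError(ValueError):
    """A response value outside the family's support was supplied."""


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _t_logpdf(z, df):
    return (
        special.gammaln(0.5 * (df + 1.0))
        - special.gammaln(0.5 * df)
        - 0.5 * np.log(df * np.pi)
        - 0.5 * (df + 1.0) * np.log1p(z * z / df)
    )


class Family:
    """Base class for response distributions (stateless; one instance each)."""

    name: str = ""
    param_names: tuple = ()
    #: (lower, upper) of the support; densities are zero outside.
    support: tuple = (-np.inf, np.inf)
    #: default link per parameter.
    default_links: dict = {}
    #: per-parameter admissible ranges, used by validation.
    param_constraints: dict = {}

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- validation --------------------------------------------------------
    def check_params(self, **params):
        """Validate a parameter set, raising ParameterError naming the offender."""
        for pname in self.param_names:
            if pname not in params or params[pname] is None:
                raise ParameterError(f"{self.name}: missing parameter {pname!r}")
        for pname, (lo, hi) in self.param_constraints.items():
            val = np.asarray(params[pname], dtype=float)
            if np.any(~np.isfinite(val)) or np.any(val <= lo) or np.any(val >= hi):
                raise ParameterError(
                    f"{self.name}: parameter {pname!r} outside admissible range "
                    f"({lo}, {hi})"
                )

    def check_support(self, y):
        y = np.asarray(y, dtype=float)
        lo, hi = self.support
        if np.any(y <= lo) or np.any(y >= hi):
            raise SupportError(
                f"{self.name}: response outside support ({lo}, {hi})"
            )

    def _prepare(self, y, params, validate):
        if validate:
            self.check_params(**params)
            self.check_support(y)
        return np.asarray(y, dtype=float)

    # -- contracts ---------------------------------------------------------
    def logpdf(self, y, validate=True, **params):
        raise NotImplementedError

    def pdf(self, y, validate=True, **params):
        return np.exp(self.logpdf(y, validate=validate, **params))

    def cdf(self, y, validate=True, **params):
        raise NotImplementedError

    def logcdf(self, y, validate=True, **params):
        with np.errstate(divide="ignore"):
            return np.log(self.cdf(y, validate=validate, **params))

    def ppf(self, q, validate=True, **params):
        raise NotImplementedError

    def rvs(self, size=1, random_state=None, validate=True, **params):
        """Inverse-transform sampling; reproducible given ``random_state``."""
        if validate:
            self.check_params(**params)
        rng = _as_rng(random_state)
        u = rng.uniform(size=size)
        return self.ppf(u, validate=False, **params)

    def _check_ppf_input(self, q):
        q = np.asarray(q, dtype=float)
        if np.any(q <= 0.0) or np.any(q >= 1.0):
            raise ValueError("quantile level must lie strictly in (0, 1)")
        return q

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Family {self.name}{self.param_names}>"


class NormalFamily(Family):
    name = "NO"
    param_names = ("mu", "sigma")
    support = (-np.inf, np.inf)
    default_links = {"mu": "identity", "sigma": "log"}
    param_constraints = {"sigma": (0.0, np.inf)}

    def logpdf(self, y, validate=True, *, mu, sigma):
        y = self._prepare(y, {"mu": mu, "sigma": sigma}, validate)
        z = (y - mu) / sigma
        return -np.log(sigma) - _HALF_LOG_2PI - 0.5 * z * z

    def cdf(self, y, validate=True, *, mu, sigma):
        y = self._prepare(y, {"mu": mu, "sigma": sigma}, validate)
        return special.ndtr((y - mu) / sigma)

    def logcdf(self, y, validate=True, *, mu, sigma):
        y = self._prepare(y, {"mu": mu, "sigma": sigma}, validate)
        return special.log_ndtr((y - mu) / sigma)

    def ppf(self, q, validate=True, *, mu, sigma):
        if validate:
            self.check_params(mu=mu, sigma=sigma)
            q = self._check_ppf_input(q)
        return mu + sigma * special.ndtri(q)

    def rvs(self, size=1, random_state=None, validate=True, *, mu, sigma):
        if validate:
            self.check_params(mu=mu, sigma=sigma)
        rng = _as_rng(random_state)
        return np.asarray(mu + sigma * rng.standard_normal(size))


def _jsu_shift_scale(sigma, nu, tau):
    """Constants of the mean/SD reparameterization of Johnson's S_u.

    With Z standard normal, ``y = mu + A + B*sinh((Z + nu)/tau)`` where the
    offset A and scale B are chosen so that E[y] = mu and SD[y] = sigma.
    Returns (rtau, B, A).
    """
    rtau = 1.0 / tau
    w = np.exp(rtau * rtau)
    omega = -nu * rtau
    c = (0.5 * (w - 1.0) * (w * np.cosh(2.0 * omega) + 1.0)) ** (-0.5)
    B = c * sigma
    A = B * np.sqrt(w) * np.sinh(omega)
    return rtau, B, A


class JSUFamily(Family):
    name = "JSU"
    param_names = ("mu", "sigma", "nu", "tau")
    support = (-np.inf, np.inf)
    default_links = {"mu": "identity", "sigma": "log", "nu": "identity", "tau": "log"}
    param_constraints = {"sigma": (0.0, np.inf), "tau": (0.0, np.inf)}

    def _z_r(self, y, mu, sigma, nu, tau):
        rtau, B, A = _jsu_shift_scale(sigma, nu, tau)
        z = (y - (mu + A)) / B
        r = -nu + np.arcsinh(z) / rtau
        return z, r, rtau, B

    def logpdf(self, y, validate=True, *, mu, sigma, nu, tau):
        y = self._prepare(y, dict(mu=mu, sigma=sigma, nu=nu, tau=tau), validate)
        z, r, rtau, B = self._z_r(y, mu, sigma, nu, tau)
        return (
            -np.log(B)
            - np.log(rtau)
            - 0.5 * np.log1p(z * z)
            - _HALF_LOG_2PI
            - 0.5 * r * r
        )

    def cdf(self, y, validate=True, *, mu, sigma, nu, tau):
        y = self._prepare(y, dict(mu=mu, sigma=sigma, nu=nu, tau=tau), validate)
        _, r, _, _ = self._z_r(y, mu, sigma, nu, tau)
        return special.ndtr(r)

    def logcdf(self, y, validate=True, *, mu, sigma, nu, tau):
        y = self._prepare(y, dict(mu=mu, sigma=sigma, nu=nu, tau=tau), validate)
        _, r, _, _ = self._z_r(y, mu, sigma, nu, tau)
        return special.log_ndtr(r)

    def ppf(self, q, validate=True, *, mu, sigma, nu, tau):
        if validate:
            self.check_params(mu=mu, sigma=sigma, nu=nu, tau=tau)
            q = self._check_ppf_input(q)
        r = special.ndtri(q)
        rtau, B, A = _jsu_shift_scale(sigma, nu, tau)
        z = np.sinh(rtau * (r + nu))
        return mu + A + B * z

    def rvs(self, size=1, random_state=None, validate=True, *, mu, sigma, nu, tau):
        if validate:
            self.check_params(mu=mu, sigma=sigma, nu=nu, tau=tau)
        rng = _as_rng(random_state)
        r = rng.standard_normal(size)
        rtau, B, A = _jsu_shift_scale(sigma, nu, tau)
        return np.asarray(mu + A + B * np.sinh(rtau * (r + nu)))


class BCTFamily(Family):
    name = "BCT"
    param_names = ("mu", "sigma", "nu", "tau")
    support = (0.0, np.inf)
    default_links = {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}
    param_constraints = {
        "mu": (0.0, np.inf),
        "sigma": (0.0, np.inf),
        "tau": (0.0, np.inf),
    }

    _NU_EPS = 1e-9

    def _z(self, y, mu, sigma, nu):
        nu = np.asarray(nu, dtype=float)
        nonzero = np.abs(nu) > self._NU_EPS
        nu_safe = np.where(nonzero, nu, 1.0)
        ratio = y / mu
        with np.errstate(over="ignore"):
            z_nonzero = (ratio ** nu_safe - 1.0) / (nu_safe * sigma)
        z_zero = np.log(ratio) / sigma
        return np.where(nonzero, z_nonzero, z_zero), nonzero, nu_safe

    def _log_norm_const(self, sigma, nu, tau, nonzero, nu_safe):
        # truncation constant F_T(1/(sigma*|nu|)); exactly 1 at nu = 0
        arg = 1.0 / (sigma * np.abs(nu_safe))
        logc = np.log(special.stdtr(tau, arg))
        return np.where(nonzero, logc, 0.0)

    def logpdf(self, y, validate=True, *, mu, sigma, nu, tau):
        y = self._prepare(y, dict(mu=mu, sigma=sigma, nu=nu, tau=tau), validate)
        z, nonzero, nu_safe = self._z(y, mu, sigma, nu)
        logc = self._log_norm_const(sigma, nu, tau, nonzero, nu_safe)
        return (
            (nu - 1.0) * np.log(y)
            - nu * np.log(mu)
            - np.log(sigma)
            + _t_logpdf(z, tau)
            - logc
        )

    def cdf(self, y, validate=True, *, mu, sigma, nu, tau):
        y = self._prepare(y, dict(mu=mu, sigma=sigma, nu=nu, tau=tau), validate)
        z, nonzero, nu_safe = self._z(y, mu, sigma, nu)
        arg = 1.0 / (sigma * np.abs(nu_safe))
        F3 = np.where(nonzero, special.stdtr(tau, arg), 1.0)
        # for nu > 0 the transform truncates z below at -1/(sigma*nu)
        F2 = np.where(np.asarray(nu) > self._NU_EPS, 1.0 - F3, 0.0)
        out = (special.stdtr(tau, z) - F2) / F3
        return np.clip(out, 0.0, 1.0)

    def ppf(self, q, validate=True, *, mu, sigma, nu, tau):
        if validate:
            self.check_params(mu=mu, sigma=sigma, nu=nu, tau=tau)
            q = self._check_ppf_input(q)
        q = np.asarray(q, dtype=float)
        nu = np.asarray(nu, dtype=float)
        nonzero = np.abs(nu) > self._NU_EPS
        nu_safe = np.where(nonzero, nu, 1.0)
        arg = 1.0 / (sigma * np.abs(nu_safe))
        F3 = np.where(nonzero, special.stdtr(tau, arg), 1.0)
        F2 = np.where(nu > self._NU_EPS, 1.0 - F3, 0.0)
        p = np.clip(q * F3 + F2, 1e-15, 1.0 - 1e-15)
        z = special.stdtrit(tau, p)
        base = 1.0 + sigma * nu_safe * z
        base = np.maximum(base, 1e-300)
        with np.errstate(over="ignore"):
            y_nonzero = mu * base ** (1.0 / nu_safe)
            y_zero = mu * np.exp(sigma * z)  # unused where nu != 0
        out = np.where(nonzero, y_nonzero, y_zero)
        return out[()] if out.ndim == 0 else out


class SkewNormalFamily(Family):
    """Azzalini's location-scale-shape skew normal."""

    name = "SN"
    param_names = ("mu", "sigma", "nu")
    support = (-np.inf, np.inf)
    default_links = {"mu": "identity", "sigma": "log", "nu": "identity"}
    param_constraints = {"sigma": (0.0, np.inf)}

    def logpdf(self, y, validate=True, *, mu, sigma, nu):
        y = self._prepare(y, dict(mu=mu, sigma=sigma, nu=nu), validate)
        z = (y - mu) / sigma
        return (
            np.log(2.0)
            - np.log(sigma)
            - _HALF_LOG_2PI
            - 0.5 * z * z
            + special.log_ndtr(nu * z)
        )

    def cdf(self, y, validate=True, *, mu, sigma, nu):
        y = self._prepare(y, dict(mu=mu, sigma=sigma, nu=nu), validate)
        z = (y - mu) / sigma
        out = special.ndtr(z) - 2.0 * special.owens_t(z, nu)
        return np.clip(out, 0.0, 1.0)

    def ppf(self, q, validate=True, *, mu, sigma, nu):
        if validate:
            self.check_params(mu=mu, sigma=sigma, nu=nu)
            q = self._check_ppf_input(q)
        return stats.skewnorm.ppf(q, nu, loc=mu, scale=sigma)

    def rvs(self, size=1, random_state=None, validate=True, *, mu, sigma, nu):
        if validate:
            self.check_params(mu=mu, sigma=sigma, nu=nu)
        rng = _as_rng(random_state)
        return np.asarray(
            stats.skewnorm.rvs(nu, loc=mu, scale=sigma, size=size, random_state=rng)
        )


class CensoredFamily:
    """Left-censored wrapper: records at/below ``cutoff`` are detection-limited.

    The likelihood contribution of a censored record is the base CDF at the
    cutoff; uncensored records contribute the base density.  Quantiles and
    random generation are defined on the base family (censoring is a feature
    of the observation process, not of the underlying distribution).
    """

    side = "left"

    def __init__(self, base: Family, cutoff: float):
        lo, hi = base.support
        if not (lo < cutoff < hi):
            raise SupportError(
                f"censoring cutoff {cutoff} outside the interior of the "
                f"{base.name} support ({lo}, {hi})"
            )
        self.base = base
        self.cutoff = float(cutoff)
        self.name = f"{base.name} left-censored at {cutoff:g}"

    @property
    def param_names(self):
        return self.base.param_names

    @property
    def default_links(self):
        return self.base.default_links

    @property
    def support(self):
        return self.base.support

    @property
    def n_params(self):
        return self.base.n_params

    def check_params(self, **params):
        self.base.check_params(**params)

    def loglik_terms(self, y, censored, validate=True, **params):
        """Per-record log-likelihood contributions.

        ``censored`` is a boolean/0-1 vector; censored records use
        log F(cutoff | params_i), uncensored records log f(y_i | params_i).
        """
        censored = np.asarray(censored, dtype=bool)
        y = np.asarray(y, dtype=float)
        # evaluate the density at the cutoff for censored rows so the base
        # support check never sees the (possibly out-of-support) stored value
        y_safe = np.where(censored, self.cutoff, y)
        dens = self.base.logpdf(y_safe, validate=validate, **params)
        cut = self.base.logcdf(np.full_like(y, self.cutoff), validate=False, **params)
        return np.where(censored, cut, dens)

    # passthroughs used by residuals and simulation
    def pdf(self, y, validate=True, **params):
        return self.base.pdf(y, validate=validate, **params)

    def logpdf(self, y, validate=True, **params):
        return self.base.logpdf(y, validate=validate, **params)

    def cdf(self, y, validate=True, **params):
        return self.base.cdf(y, validate=validate, **params)

    def logcdf(self, y, validate=True, **params):
        return self.base.logcdf(y, validate=validate, **params)

    def ppf(self, q, validate=True, **params):
        return self.base.ppf(q, validate=validate, **params)

    def rvs(self, size=1, random_state=None, validate=True, **params):
        return self.base.rvs(size=size, random_state=random_state,
                             validate=validate, **params)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CensoredFamily {self.name}>"


def censor_left(base, cutoff: float) -> CensoredFamily:
    """Left-censor ``base`` at ``cutoff`` (e.g. an assay detection limit)."""
    if isinstance(base, str):
        base = get_family(base)
    return CensoredFamily(base, cutoff)


FAMILY_REGISTRY = {
    "NO": NormalFamily(),
    "JSU": JSUFamily(),
    "BCT": BCTFamily(),
    "SN": SkewNormalFamily(),
}


def get_family(name):
    """Resolve a family by registry name ("NO", "JSU", "BCT", "SN")."""
    if isinstance(name, (Family, CensoredFamily)):
        return name
    try:
        return FAMILY_REGISTRY[str(name).upper()]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; available: {sorted(FAMILY_REGISTRY)}"
        ) from None
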