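"""Synthetic two-arm trial generator.

The real trial data are not public, so every Monte-Carlo study in this
package runs on trials generated here.  A :class:`GeneratorConfig` fixes the
study conditions: number of participants, treatment allocation, a positive
baseline law standing in for the baseline biomarker (default: log-normal
with median 0.65 nmol/L and log-scale SD 0.25, emulating an MR-proADM-like
marker), a binary sex covariate (prevalence 0.8, the trial being
predominantly male), a response family with a per-parameter coefficient set,
and an optional left-censoring cutoff (0.05 nmol/L, the MR-proADM detection
limit).  Responses are drawn from the family with row-wise parameters
computed through the links; censoring is applied last, storing censored
responses at the cutoff with a flag, as detection-limit data are entered in
practice.

``gen_longitudinal`` adds repeated visits with a shared Gaussian subject
intercept on the mu predictor, inducing within-subject correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .coefsets import get_coefset
from .design import DesignError, TrialDataset, evaluate_term
from .families import get_family
from .links import get_link

__all__ = ["BaselineLaw", "GeneratorConfig", "gen_baseline", "gen_trial",
           "gen_longitudinal"]


@dataclass(frozen=True)
class BaselineLaw:
    """Distribution of the baseline covariate.

    Kinds: ``lognormal`` (params: meanlog, sdlog) and ``truncnormal``
    (params: mean, sd; normal truncated to (0, inf)).  Both have positive
    support, as required of a baseline biomarker.
    """

    kind: str = "lognormal"
    params: tuple = (np.log(0.65), 0.25)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "lognormal":
            meanlog, sdlog = self.params
            if sdlog < 0:
                raise ValueError("lognormal sdlog must be >= 0")
            if sdlog == 0:
                return np.full(n, np.exp(meanlog))
            return rng.lognormal(meanlog, sdlog, n)
        if self.kind == "truncnormal":
            mean, sd = self.params
            if sd < 0:
                raise ValueError("truncnormal sd must be >= 0")
            if sd == 0:
                if mean <= 0:
                    raise ValueError("degenerate truncnormal at a "
                                     "non-positive value")
                return np.full(n, float(mean))
            out = rng.normal(mean, sd, n)
            bad = out <= 0
            while bad.any():  # resample the (vanishingly rare) tail
                out[bad] = rng.normal(mean, sd, int(bad.sum()))
                bad = out <= 0
            return out
        raise ValueError(
            f"unknown or non-positive-support baseline law {self.kind!r}"
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of one synthetic trial scenario."""

    n: int = 2000
    family: str = "BCT"
    #: per-parameter {term: coefficient}; terms use design syntax
    coefficients: dict = field(default_factory=dict)
    links: dict = field(default_factory=dict)
    baseline_law: BaselineLaw = BaselineLaw()
    #: probability of treatment allocation (independent Bernoulli)
    allocation: float = 0.5
    #: prevalence of the binary sex covariate; None drops the column
    sex_prevalence: Optional[float] = 0.8
    censor_cutoff: Optional[float] = None
    seed: Optional[int] = None

    @classmethod
    def from_coefset(cls, name: str, **overrides) -> "GeneratorConfig":
        """Build a config from a shipped coefficient set by name."""
        cs = get_coefset(name)
        cfg = cls(
            family=cs["family"],
            coefficients={p: dict(v) for p, v in cs["coefficients"].items()},
            links=dict(cs.get("links", {})),
        )
        if cs["family"] == "JSU":  # SBP scenarios use a blood-pressure baseline
            cfg = replace(cfg, baseline_law=BaselineLaw("truncnormal",
                                                        (140.0, 18.0)))
        return replace(cfg, **overrides)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "family": self.family,
            "coefficients": {p: dict(v) for p, v in self.coefficients.items()},
            "links": dict(self.links),
            "baseline_law": {"kind": self.baseline_law.kind,
                             "params": list(self.baseline_law.params)},
            "allocation": self.allocation,
            "sex_prevalence": self.sex_prevalence,
            "censor_cutoff": self.censor_cutoff,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        law = d.get("baseline_law", {})
        return cls(
            n=int(d.get("n", 2000)),
            family=d.get("family", "BCT"),
            coefficients={p: dict(v)
                          for p, v in d.get("coefficients", {}).items()},
            links=dict(d.get("links", {})),
            baseline_law=BaselineLaw(law.get("kind", "lognormal"),
                                     tuple(law.get("params",
                                                   (np.log(0.65), 0.25)))),
            allocation=float(d.get("allocation", 0.5)),
            sex_prevalence=d.get("sex_prevalence", 0.8),
            censor_cutoff=d.get("censor_cutoff"),
            seed=d.get("seed"),
        )


def gen_baseline(n: int, law: BaselineLaw = BaselineLaw(),
                 seed=None) -> np.ndarray:
    """Positive baseline covariate vector, reproducible given ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return law.sample(int(n), rng)


def _row_params(config: GeneratorConfig, df: pd.DataFrame):
    """Distribution parameters per row via the configured links."""
    fam = get_family(config.family)
    params = {}
    for pname in fam.param_names:
        coefs = config.coefficients.get(pname)
        if not coefs:
            raise DesignError(
                f"generator coefficients missing for parameter {pname!r}"
            )
        eta = np.zeros(len(df))
        for term, beta in coefs.items():
            eta += beta * evaluate_term(df, term)
        link = get_link(config.links.get(pname, fam.default_links[pname]))
        vals = link.inverse(eta)
        lo, hi = fam.param_constraints.get(pname, (-np.inf, np.inf))
        bad = ~np.isfinite(vals) | (vals <= lo) | (vals >= hi)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DesignError(
                f"link inverse yields inadmissible {pname!r} at row {row} "
                f"(value {vals[row]!r})"
            )
        params[pname] = vals
    return fam, params


def _covariate_frame(config: GeneratorConfig, rng) -> pd.DataFrame:
    n = int(config.n)
    df = pd.DataFrame({
        "id": np.arange(n),
        "treatment": rng.binomial(1, config.allocation, n),
        "baseline": config.baseline_law.sample(n, rng),
    })
    if config.sex_prevalence is not None:
        df["sex"] = rng.binomial(1, config.sex_prevalence, n)
    return df


def _apply_censoring(df: pd.DataFrame, cutoff) -> pd.DataFrame:
    if cutoff is None:
        df["censored"] = 0
        return df
    below = df["response"].to_numpy() <= cutoff
    df["censored"] = below.astype(int)
    df.loc[below, "response"] = cutoff
    return df


def gen_trial(config: GeneratorConfig, seed=None) -> TrialDataset:
    """One cross-sectional two-arm trial drawn under ``config``.

    Per row: treatment ~ Bernoulli(allocation) independent of baseline,
    baseline from the configured law, distribution parameters through the
    links, response via the family's random generator, censoring applied
    last (censored rows stored at the cutoff with ``censored = 1``).
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    df = _covariate_frame(config, rng)
    fam, params = _row_params(config, df)
    df["response"] = fam.rvs(size=len(df), random_state=rng, validate=False,
                             **params)
    df["visit"] = 0
    df = _apply_censoring(df, config.censor_cutoff)
    return TrialDataset(df)


def gen_longitudinal(config: GeneratorConfig, months=(48, 72),
                     random_sd: float = 10.712, seed=None) -> TrialDataset:
    """A longitudinal trial: one row per subject-visit.

    Visit indicators ``month_<m>`` (the first month is the reference level)
    may appear in the coefficient sets for any parameter.  A shared Gaussian
    intercept with standard deviation ``random_sd`` is added to each
    subject's mu predictor across all of that subject's rows.
    """
    if len(months) < 2:
        raise ValueError("longitudinal generation needs at least 2 visits")
    if random_sd < 0:
        raise ValueError("random_sd must be >= 0")
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    subj = _covariate_frame(config, rng)
    b = rng.normal(0.0, random_sd, len(subj)) if random_sd > 0 \
        else np.zeros(len(subj))
    rows = []
    for m in months:
        block = subj.copy()
        block["visit"] = m
        for other in months[1:]:
            block[f"month_{other}"] = int(m == other)
        rows.append(block)
    df = pd.concat(rows, ignore_index=True)
    fam, params = _row_params(config, df)
    # random intercept enters the mu predictor on the link scale
    mu_link = get_link(config.links.get("mu", fam.default_links["mu"]))
    eta_mu = mu_link.forward(params["mu"]) + np.tile(b, len(months))
    params["mu"] = mu_link.inverse(eta_mu)
    df["response"] = fam.rvs(size=len(df), random_state=rng, validate=False,
                             **params)
    df = _apply_censoring(df, config.censor_cutoff)
    df = df.sort_values(["id", "visit"]).reset_index(drop=True)
    return TrialDataset(df)
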