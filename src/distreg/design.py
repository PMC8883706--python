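"""Trial data container, model specification, and design-matrix construction.

A term in a per-parameter predictor is either the implicit intercept
``"(Intercept)"``, a column name of the dataset (``"treatment"``, ``"sex"``,
``"baseline"``, ...), or a log-transformed column written ``"log(col)"``.
Every parameter of the family always gets an intercept; additional terms are
listed per parameter in :class:`ModelSpec`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .families import CensoredFamily, get_family

__all__ = [
    "INTERCEPT",
    "TrialDataset",
    "ModelSpec",
    "build_design",
    "evaluate_term",
    "DesignError",
]

INTERCEPT = "(Intercept)"
_LOG_TERM = re.compile(r"^log\(([^()]+)\)$")


class DesignError(ValueError):
    """A model term cannot be built from the supplied dataset."""


class TrialDataset:
    """One row per observation of a two-arm trial.

    Required columns: ``response`` (continuous outcome) and ``treatment``
    (0/1 indicator).  Optional: ``id`` (subject identifier for longitudinal
    data), ``visit`` (visit label), ``censored`` (0/1 detection-limit flag,
    defaulted to all-zero), plus any covariate columns.  Rows with a missing
    response are dropped and counted; missing values anywhere else are an
    error, so downstream code never sees NaN.
    """

    def __init__(self, data: pd.DataFrame, response: str = "response",
                 treatment: str = "treatment", censored: str = "censored"):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        for col in (response, treatment):
            if col not in data.columns:
                raise DesignError(f"required column {col!r} missing from data")
        df = data.copy()
        missing = df[response].isna()
        self.n_dropped = int(missing.sum())
        if self.n_dropped:
            df = df.loc[~missing]
        if df.drop(columns=[response]).isna().any().any():
            bad = [c for c in df.columns if df[c].isna().any()]
            raise DesignError(f"missing values in columns {bad}")
        tr = np.asarray(df[treatment])
        if not np.isin(tr, (0, 1)).all():
            rows = np.flatnonzero(~np.isin(tr, (0, 1)))[:10]
            raise DesignError(
                f"treatment must be 0/1; offending rows (0-based): {rows.tolist()}"
            )
        if censored not in df.columns:
            df = df.assign(**{censored: 0})
        cz = np.asarray(df[censored])
        if not np.isin(cz, (0, 1)).all():
            raise DesignError("censored flag must be 0/1")
        df = df.reset_index(drop=True)
        self.df = df
        self.response_col = response
        self.treatment_col = treatment
        self.censored_col = censored

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def response(self) -> np.ndarray:
        return self.df[self.response_col].to_numpy(dtype=float)

    @property
    def treatment(self) -> np.ndarray:
        return self.df[self.treatment_col].to_numpy(dtype=int)

    @property
    def censored(self) -> np.ndarray:
        return self.df[self.censored_col].to_numpy(dtype=int)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    def subject_codes(self, column: str):
        """Integer subject codes and number of subjects for a grouping column."""
        if column not in self.df.columns:
            raise DesignError(f"subject column {column!r} missing from data")
        codes, uniques = pd.factorize(self.df[column], sort=True)
        return codes.astype(np.intp), len(uniques)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TrialDataset n={self.n} censored={self.n_censored}>"


@dataclass(frozen=True)
class ModelSpec:
    """Per-parameter term lists, link overrides, censoring and random intercept.

    ``mu``/``sigma``/``nu``/``tau`` list terms *besides* the intercept, which
    is always included for every parameter the family has.  ``links`` may
    override the family defaults per parameter.  ``random_intercept`` names
    the subject-id column for a Gaussian random intercept on the mu predictor
    (the only parameter where one is supported).
    """

    family: str = "NO"
    mu: tuple = ()
    sigma: tuple = ()
    nu: tuple = ()
    tau: tuple = ()
    links: dict = field(default_factory=dict)
    censor_cutoff: float | None = None
    random_intercept: str | None = None

    def terms(self, param: str) -> tuple:
        return (INTERCEPT,) + tuple(getattr(self, param))

    def resolved_family(self):
        """The (possibly censored) family instance this spec fits."""
        from .families import censor_left

        fam = get_family(self.family)
        if self.censor_cutoff is not None:
            fam = censor_left(fam, self.censor_cutoff)
        return fam

    def validate(self, data: TrialDataset):
        fam = self.resolved_family()
        for param in ("mu", "sigma", "nu", "tau"):
            tl = getattr(self, param)
            if tl and param not in fam.param_names:
                raise DesignError(
                    f"family {fam.name} has no parameter {param!r}"
                )
            for term in tl:
                _term_column(term)  # syntax check
        for param, link in self.links.items():
            if param not in fam.param_names:
                raise DesignError(f"link override for unknown parameter {param!r}")
        if self.random_intercept is not None and "mu" not in fam.param_names:
            raise DesignError("random intercept requires a mu parameter")
        return self

    def without_terms(self, param: str, drop: tuple) -> "ModelSpec":
        """A nested spec with the given terms removed from one parameter."""
        kept = tuple(t for t in getattr(self, param) if t not in drop)
        return replace(self, **{param: kept})

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mu": list(self.mu),
            "sigma": list(self.sigma),
            "nu": list(self.nu),
            "tau": list(self.tau),
            "links": dict(self.links),
            "censor_cutoff": self.censor_cutoff,
            "random_intercept": self.random_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            family=d.get("family", "NO"),
            mu=tuple(d.get("mu", ())),
            sigma=tuple(d.get("sigma", ())),
            nu=tuple(d.get("nu", ())),
            tau=tuple(d.get("tau", ())),
            links=dict(d.get("links", {})),
            censor_cutoff=d.get("censor_cutoff"),
            random_intercept=d.get("random_intercept"),
        )


def _term_column(term: str):
    """The dataset column a term refers to, and whether it is log-transformed."""
    if term == INTERCEPT:
        return None, False
    m = _LOG_TERM.match(term)
    if m:
        return m.group(1).strip(), True
    return term, False


def evaluate_term(df: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate one model term on a data frame (vector of length n)."""
    col, do_log = _term_column(term)
    if col is None:
        return np.ones(len(df))
    if col not in df.columns:
        raise DesignError(f"unknown covariate {col!r} in term {term!r}")
    vals = df[col].to_numpy(dtype=float)
    if do_log:
        if np.any(vals <= 0):
            rows = np.flatnonzero(vals <= 0)[:10]
            raise DesignError(
                f"log-transform of non-positive values in {col!r}; "
                f"offending rows (0-based): {rows.tolist()}"
            )
        vals = np.log(vals)
    return vals


def build_design(data: TrialDataset, spec: ModelSpec):
    """Design matrices per family parameter.

    Returns ``{param: (X, column_names)}`` with the intercept first and the
    remaining columns in spec order.
    """
    if not isinstance(data, TrialDataset):
        data = TrialDataset(data)
    spec.validate(data)
    fam = spec.resolved_family()
    out = {}
    for param in fam.param_names:
        names = spec.terms(param)
        cols = [evaluate_term(data.df, t) for t in names]
        out[param] = (np.column_stack(cols), list(names))
    return out
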