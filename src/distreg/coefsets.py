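"""Shipped coefficient sets for the synthetic-trial generator.

These are the fitted coefficient sets of the published LIPID analyses of
12-month MR-proADM (left-censored normal and Box-Cox-t models) and of change
in systolic blood pressure at 72 months (Johnson S_u), plus the longitudinal
random-intercept S_u model for months 48 and 72.  They define the generating
conditions of the Monte-Carlo studies: a generator configured with one of
these sets emulates a trial whose outcome follows the corresponding fitted
model.

Coefficient keys follow the design-term syntax: ``(Intercept)``,
``treatment``, ``sex``, ``log(baseline)`` (log of baseline biomarker),
``baseline`` (raw baseline SBP), ``month_72`` (visit indicator).
"""

from __future__ import annotations

__all__ = ["COEFSETS", "get_coefset"]

# MR-proADM (nmol/L) at month 12; baseline enters mu on the log scale and,
# in the extended models, also sigma/nu/tau on the log scale.  The normal
# models use an identity mu link; the BCT models a log mu link.
MRPROADM_REDUCED_NORMAL = {
    "family": "NO",
    "links": {"mu": "identity", "sigma": "log"},
    "coefficients": {
        "mu": {"(Intercept)": 0.668, "log(baseline)": 0.236,
               "treatment": -0.005},
        "sigma": {"(Intercept)": -1.818},
    },
}

MRPROADM_EXTENDED_NORMAL = {
    "family": "NO",
    "links": {"mu": "identity", "sigma": "log"},
    "coefficients": {
        "mu": {"(Intercept)": 0.745, "log(baseline)": 0.319,
               "treatment": -0.005},
        "sigma": {"(Intercept)": -1.890, "log(baseline)": -0.230,
                  "sex": -0.154},
    },
}

MRPROADM_REDUCED_BCT = {
    "family": "BCT",
    "links": {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"},
    "coefficients": {
        "mu": {"(Intercept)": -0.129, "log(baseline)": 0.813,
               "treatment": -0.014},
        "sigma": {"(Intercept)": -1.959},
        "nu": {"(Intercept)": 0.426},
        "tau": {"(Intercept)": 0.287},
    },
}

MRPROADM_EXTENDED_BCT = {
    "family": "BCT",
    "links": {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"},
    "coefficients": {
        "mu": {"(Intercept)": -0.088, "log(baseline)": 0.879, "sex": -0.017,
               "treatment": -0.018},
        "sigma": {"(Intercept)": -2.796, "log(baseline)": -1.426,
                  "sex": -0.158, "treatment": 0.073},
        "nu": {"(Intercept)": 1.109, "log(baseline)": 0.153,
               "treatment": 0.124},
        "tau": {"(Intercept)": -0.029, "log(baseline)": -1.184},
    },
}

# Change in SBP (mmHg) at month 72; baseline is raw baseline SBP.
SBP_REDUCED_JSU = {
    "family": "JSU",
    "links": {"mu": "identity", "sigma": "log", "nu": "identity",
              "tau": "log"},
    "coefficients": {
        "mu": {"(Intercept)": 82.142, "baseline": -0.609,
               "treatment": 0.514},
        "sigma": {"(Intercept)": 2.867},
        "nu": {"(Intercept)": 1.259},
        "tau": {"(Intercept)": 1.057},
    },
}

SBP_EXTENDED_JSU = {
    "family": "JSU",
    "links": {"mu": "identity", "sigma": "log", "nu": "identity",
              "tau": "log"},
    "coefficients": {
        "mu": {"(Intercept)": 79.722, "baseline": -0.589,
               "treatment": 0.042},
        "sigma": {"(Intercept)": 2.473, "baseline": 0.003,
                  "treatment": -0.067},
        "nu": {"(Intercept)": 4.018, "baseline": -0.018},
        "tau": {"(Intercept)": 1.160},
    },
}

# Longitudinal change in SBP at months 48 and 72; Gaussian random intercept
# on the mu predictor (SD on the natural scale).
SBP_LONGITUDINAL_JSU = {
    "family": "JSU",
    "links": {"mu": "identity", "sigma": "log", "nu": "identity",
              "tau": "log"},
    "coefficients": {
        "mu": {"(Intercept)": 79.238, "baseline": -0.592, "month_72": 0.747,
               "treatment": 0.200},
        "sigma": {"(Intercept)": 1.862, "baseline": 0.005, "month_72": 0.042,
                  "treatment": -0.048},
        "nu": {"(Intercept)": 5.354, "baseline": -0.026},
        "tau": {"(Intercept)": 0.950},
    },
    "random_intercept_sd": 10.712,
}

COEFSETS = {
    "mrproadm_reduced_normal": MRPROADM_REDUCED_NORMAL,
    "mrproadm_extended_normal": MRPROADM_EXTENDED_NORMAL,
    "mrproadm_reduced_bct": MRPROADM_REDUCED_BCT,
    "mrproadm_extended_bct": MRPROADM_EXTENDED_BCT,
    "sbp_reduced_jsu": SBP_REDUCED_JSU,
    "sbp_extended_jsu": SBP_EXTENDED_JSU,
    "sbp_longitudinal_jsu": SBP_LONGITUDINAL_JSU,
}


def get_coefset(name: str) -> dict:
    try:
        return COEFSETS[name]
    except KeyError:
        raise KeyError(
            f"unknown coefficient set {name!r}; available: {sorted(COEFSETS)}"
        ) from None
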