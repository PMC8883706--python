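"""Link functions mapping distribution parameters to unconstrained predictors.

Only the identity and log links are needed for the families implemented here:
identity for real-valued location/shape parameters, log for strictly positive
scale/kurtosis parameters (and for positive-support medians).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Link", "IdentityLink", "LogLink", "get_link", "LINKS"]

# exp() overflows past ~709; predictors are clipped so the inverse link can
# never produce inf inside the optimizer.
_ETA_MAX = 300.0


class Link:
    """A monotone differentiable map parameter -> linear predictor."""

    name: str = ""

    def forward(self, param):
        """Parameter scale -> predictor scale (g)."""
        raise NotImplementedError

    def inverse(self, eta):
        """Predictor scale -> parameter scale (g^-1)."""
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}()"


class IdentityLink(Link):
    name = "identity"

    def forward(self, param):
        return np.asarray(param, dtype=float)

    def inverse(self, eta):
        return np.asarray(eta, dtype=float)


class LogLink(Link):
    name = "log"

    def forward(self, param):
        param = np.asarray(param, dtype=float)
        if np.any(param <= 0):
            raise ValueError("log link requires a strictly positive parameter")
        return np.log(param)

    def inverse(self, eta):
        eta = np.asarray(eta, dtype=float)
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


LINKS = {"identity": IdentityLink(), "log": LogLink()}


def get_link(name) -> Link:
    if isinstance(name, Link):
        return name
    try:
        return LINKS[name]
    except KeyError:
        raise KeyError(f"unknown link {name!r}; available: {sorted(LINKS)}") from None
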