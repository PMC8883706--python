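"""Tabular and JSON input/output plus run manifests.

CSV dialect: comma-separated, header row, UTF-8, "." decimal.  Numbers are
serialized at full double precision; display rounding happens only in
``summary()`` tables.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignError, ModelSpec, TrialDataset
from .model import DistributionalModel, DistributionalResults
from .study import StudyResult

__all__ = [
    "read_trial_csv",
    "write_fit_json",
    "read_fit_json",
    "results_from_fit_json",
    "write_residuals_csv",
    "write_study_result",
    "read_study_records",
    "write_manifest",
]


def read_trial_csv(path, response: str = "response",
                   treatment: str = "treatment") -> TrialDataset:
    """Read a trial CSV into a validated :class:`TrialDataset`.

    Rows with a missing response are dropped and counted
    (``dataset.n_dropped``); a missing ``censored`` column defaults to
    all-zero.
    """
    df = pd.read_csv(path)
    try:
        return TrialDataset(df, response=response, treatment=treatment)
    except DesignError as exc:
        raise DesignError(f"{path}: {exc}") from exc


def write_fit_json(fit: DistributionalResults, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())


def results_from_fit_json(fit_dict: dict, data) -> DistributionalResults:
    """Rebuild a results object from a serialized fit and its dataset.

    The stored coefficient vector is reused as-is (no refitting); standard
    errors and covariance come from the stored values where present.
    """
    spec = ModelSpec.from_dict(fit_dict["spec"])
    model = DistributionalModel(data, spec)
    theta = np.array([fit_dict["coefficients"][name]
                      for name in model.coef_names], dtype=float)
    se = np.array([np.nan if fit_dict["se"].get(name) is None
                   else fit_dict["se"][name]
                   for name in model.coef_names], dtype=float)
    k = len(theta)
    cov = np.full((k, k), np.nan)
    np.fill_diagonal(cov, se**2)
    return DistributionalResults(
        model, theta, fit_dict["loglik"], cov, se,
        fit_dict.get("converged", True), fit_dict.get("iterations", 0),
        fit_dict.get("message", "restored"), cov_ok=bool(np.isfinite(se).all()),
    )


def write_residuals_csv(residual_set, path) -> None:
    pd.DataFrame({
        "row": np.arange(len(residual_set)),
        "residual": residual_set.residuals,
        "randomized": residual_set.randomized,
    }).to_csv(path, index=False)


def write_study_result(result: StudyResult, path) -> None:
    """JSON aggregates next to a per-replicate CSV (``<path>`` and
    ``<path stem>.records.csv``)."""
    if result.records.empty:
        raise ValueError("empty study result: nothing to write")
    path = Path(path)
    payload = result.to_dict()
    csv_path = path.with_suffix(".records.csv")
    payload["records_csv"] = csv_path.name
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    result.records.to_csv(csv_path, index=False)


def read_study_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(command: str, config, seed, inputs, outputs) -> None:
    """Write a run manifest next to the first output path."""
    from . import __version__

    outputs = [str(p) for p in outputs]
    manifest = {
        "command": command,
        "config_digest": _digest(config),
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": [str(p) for p in inputs],
        "outputs": outputs,
    }
    target = Path(outputs[0]).with_suffix(Path(outputs[0]).suffix +
                                          ".manifest.json")
    target.write_text(json.dumps(manifest, indent=2) + "\n")
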