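"""Loaders for the packaged Canadian estimation fixtures.

The package ships the published Canadian conditional-logit coefficient
tables (unweighted, raked, and raked-with-monotonicity-imposed) and the
published value set.  These are reference data for cross-checks, true
preferences for simulation, and the default scoring weights — they are
never outputs of this package's own estimation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .clogit import ModelSpec
from .descriptive import DIMENSIONS

_DATA = Path(__file__).parent / "data"


def published_coefficients(model: str = "model3") -> dict:
    """Published coefficient table for 'model1', 'model2' or 'model3'.

    Returns alpha, per-level beta arrays, log-likelihood, parameter count
    and information criteria as printed.
    """
    payload = json.loads((_DATA / "conditional_logit_coefficients.json").read_text())
    if model not in payload or model == "notes":
        raise KeyError(f"unknown model {model!r}; choose model1, model2 or model3")
    entry = dict(payload[model])
    entry["beta"] = {d: np.asarray(v, float) for d, v in entry["beta"].items()}
    return entry


def published_model_spec() -> ModelSpec:
    """The published constrained model's level-collapsing pattern (23 parameters)."""
    payload = json.loads((_DATA / "conditional_logit_coefficients.json").read_text())
    return ModelSpec.from_dict(payload["model3"]["spec"])


def published_parameter_map(model: str = "model2",
                            spec: ModelSpec | None = None) -> dict[str, float]:
    """Published coefficients keyed by this package's parameter names.

    With the default full specification each level maps to its own
    parameter; with a collapsed spec each group takes the (shared) value of
    its levels.
    """
    entry = published_coefficients(model)
    spec = spec or ModelSpec.full()
    out = {"duration": float(entry["alpha"])}
    for dim in DIMENSIONS:
        beta = entry["beta"][dim]
        for g in spec.dimensions[dim]:
            if g.to_reference:
                continue
            vals = {float(beta[l - 1]) for l in g.levels}
            if len(vals) != 1:
                raise ValueError(f"{dim} {g.label}: published levels disagree; "
                                 "spec does not match the published pattern")
            out[f"{dim}:{g.label}"] = vals.pop()
    return out
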