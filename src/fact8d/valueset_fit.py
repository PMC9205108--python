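"""From conditional-logit coefficients to a monotone value set.

An unconstrained fit can violate the logical ordering of severity levels
in two ways: a level coefficient can be positive (a worse-than-reference
level implying a utility *gain*) or an adjacent, more severe level can
carry a less negative coefficient than a milder one.  The constraint loop
collapses offending levels and refits until the coefficient profile is
monotone: a positive group adjacent to the reference merges into the
reference (coefficient pinned at 0); a reversed adjacent pair merges into
one shared group.  All violations found in a round are applied together,
mildest level first within each dimension, then the model is refit.

Anchoring converts coefficients to utility decrements by the marginal
rate of substitution with duration: ``w_dl = -beta_dl / alpha`` expresses
each level's disutility as the fraction of remaining life-years a
respondent would give up to avoid it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import clogit
from .clogit import FitResult, FitError, ModelSpec
from .descriptive import DIMENSIONS, ValueSet
from .weights import WeightVector


class ConstraintError(RuntimeError):
    def __init__(self, message: str, residual: list["ViolationRecord"]):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ViolationRecord:
    """One monotonicity violation in a fitted coefficient profile."""

    dimension: str
    kind: str                       # "positive" or "reversed"
    levels: tuple[int, ...]         # levels of the offending group
    coefficient: float
    milder_levels: tuple[int, ...] | None = None  # for "reversed": the milder group
    milder_coefficient: float | None = None

    def describe(self) -> str:
        lv = "/".join(map(str, self.levels))
        if self.kind == "positive":
            return (f"{self.dimension} level {lv}: coefficient "
                    f"{self.coefficient:+.4f} >= 0 (worse level implies utility gain)")
        ml = "/".join(map(str, self.milder_levels or ()))
        return (f"{self.dimension} level {lv} ({self.coefficient:+.4f}) preferred to "
                f"milder level {ml} ({self.milder_coefficient:+.4f})")


def _group_coefficients(coefs: Mapping[str, float], spec: ModelSpec,
                        dim: str) -> list[tuple[int, tuple[int, ...], float]]:
    """Estimated groups of one dimension as (group index, levels, coefficient)."""
    out = []
    for i, g in enumerate(spec.dimensions[dim]):
        if not g.to_reference:
            out.append((i, g.levels, float(coefs[f"{dim}:{g.label}"])))
    return out


def detect_violations(fit: FitResult | Mapping[str, float],
                      spec: ModelSpec | None = None) -> list[ViolationRecord]:
    """Flag positive and order-reversed level coefficients.

    Accepts either a `FitResult` (spec taken from it) or a plain mapping of
    parameter names to coefficients together with an explicit spec.
    Records are ordered mildest level first within each dimension,
    dimensions in canonical order.
    """
    if isinstance(fit, FitResult):
        coefs, spec = fit.coefficients(), fit.spec
    else:
        if spec is None:
            raise ValueError("a spec is required with a plain coefficient mapping")
        coefs = dict(fit)
    records: list[ViolationRecord] = []
    for dim in DIMENSIONS:
        est = _group_coefficients(coefs, spec, dim)
        for pos, (_, levels, coef) in enumerate(est):
            if coef >= 0:
                records.append(ViolationRecord(dim, "positive", levels, coef))
            if pos > 0:
                _, milder_levels, milder_coef = est[pos - 1]
                if coef > milder_coef:
                    records.append(ViolationRecord(
                        dim, "reversed", levels, coef,
                        milder_levels=milder_levels, milder_coefficient=milder_coef,
                    ))
    return records


def _merge_round(spec: ModelSpec, coefs: Mapping[str, float]) -> tuple[ModelSpec, list[dict]]:
    """Apply one round of merges; returns the new spec and an action log."""
    actions: list[dict] = []
    for dim in DIMENSIONS:
        est = _group_coefficients(coefs, spec, dim)
        handled: set[int] = set()
        ops: list[tuple[str, int, tuple[int, ...]]] = []
        groups = spec.dimensions[dim]
        for pos, (i, levels, coef) in enumerate(est):
            if i in handled:
                continue
            adjacent_to_ref = all(g.to_reference for g in groups[:i])
            if coef >= 0 and adjacent_to_ref:
                ops.append(("to_reference", i, levels))
                handled.add(i)
                continue
            if pos > 0:
                i_prev, prev_levels, prev_coef = est[pos - 1]
                if i_prev not in handled and coef > prev_coef:
                    ops.append(("merge_pair", i_prev, prev_levels + levels))
                    handled.update({i, i_prev})
        # descending index order keeps earlier indices valid across pair merges
        for action, idx, levels in sorted(ops, key=lambda o: -o[1]):
            if action == "to_reference":
                spec = spec.merge_group_to_reference(dim, idx)
            else:
                spec = spec.merge_adjacent(dim, idx)
            actions.append({"dimension": dim, "action": action,
                            "levels": list(levels)})
    return spec, actions


def constrain(
    dataset: pd.DataFrame,
    spec: ModelSpec | None = None,
    weights: WeightVector | None = None,
    *,
    max_rounds: int = 10,
    forced_spec: ModelSpec | None = None,
) -> tuple[ModelSpec, FitResult, list[dict]]:
    """Iteratively collapse non-monotone levels until the fit is consistent.

    Returns ``(final spec, final fit, merge history)`` where the history is
    a list of rounds, each a list of merge actions.  A monotone initial fit
    returns unchanged (idempotent).  ``forced_spec`` skips detection and
    fits a user-supplied collapsing pattern directly (e.g. to reproduce a
    published constrained model).  The constrained log-likelihood can never
    exceed the unconstrained one (nested maximization).
    """
    spec = spec or ModelSpec.full()
    if forced_spec is not None:
        result = clogit.fit(dataset, forced_spec, weights)
        return forced_spec, result, [[{"dimension": None, "action": "forced",
                                       "levels": []}]]
    history: list[list[dict]] = []
    result = clogit.fit(dataset, spec, weights)
    for _ in range(max_rounds):
        violations = detect_violations(result)
        if not violations:
            return spec, result, history
        spec, actions = _merge_round(spec, result.coefficients())
        history.append(actions)
        result = clogit.fit(dataset, spec, weights)
    violations = detect_violations(result)
    if violations:
        raise ConstraintError(
            f"{len(violations)} violations remain after {max_rounds} rounds: "
            + "; ".join(v.describe() for v in violations),
            residual=violations,
        )
    return spec, result, history


def derive_value_set(fit: FitResult, *, label: str = "derived",
                     country: str = "", source_model: str = "") -> ValueSet:
    """Convert fitted coefficients to utility decrements via MRS anchoring.

    ``w_dl = -beta_dl / alpha``, expanded to all five levels through the
    spec's groups: reference-merged levels get decrement 0 and pair-merged
    levels share a value.  Requires ``alpha > 0`` (anchoring is undefined
    when life-years carry no positive utility) and a violation-free
    coefficient profile (run `constrain` first).
    """
    if not fit.alpha > 0:
        raise FitError(f"alpha = {fit.alpha:.4f} <= 0: MRS anchoring undefined")
    _, beta = fit.spec.expand(fit.params)
    decrements = {d: -beta[d] / fit.alpha for d in DIMENSIONS}
    # strictly positive coefficients (negative decrements) or reversed
    # orderings cannot form a value set; zero coefficients are fine
    bad = [d for d in DIMENSIONS
           if (decrements[d] < 0).any() or (np.diff(decrements[d]) < 0).any()]
    if bad:
        raise FitError(
            "cannot derive a value set from a non-monotone fit "
            f"(offending dimensions: {bad}); run the constraint loop first"
        )
    return ValueSet(decrements=decrements, label=label, country=country,
                    source_model=source_model or
                    f"conditional logit ({fit.n_parameters} parameters, "
                    f"{'weighted' if fit.weighted else 'unweighted'})")


@dataclass(frozen=True)
class FitComparison:
    """Paired coefficient estimates from two fits of the same specification."""

    table: pd.DataFrame
    max_abs_difference: float
    sign_agreements: int
    n_parameters: int

    @property
    def all_signs_agree(self) -> bool:
        return self.sign_agreements == self.n_parameters


def compare_fits(a: FitResult, b: FitResult) -> FitComparison:
    """Numeric stand-in for the unweighted-vs-weighted scatter comparison."""
    if a.names != b.names:
        raise ValueError("fits use different specifications; cannot compare")
    table = pd.DataFrame({
        "estimate_a": a.params, "se_a": a.se,
        "estimate_b": b.params, "se_b": b.se,
        "difference": b.params - a.params,
    }, index=pd.Index(a.names, name="parameter"))
    signs = int(np.sum(np.sign(a.params) == np.sign(b.params)))
    return FitComparison(
        table=table,
        max_abs_difference=float(np.max(np.abs(table["difference"]))),
        sign_agreements=signs,
        n_parameters=len(a.names),
    )
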