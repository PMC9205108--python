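"""Survey representativeness checks and raked (iterative proportional fitting) weights.

A variable is flagged non-representative when any of its levels deviates
from the population margin by at least 2 percentage points; flagged
variables are raked so that weighted sample margins reproduce the
population margins.  Raking multiplies each respondent's weight by the
target/observed margin ratio of their level, cycling over variables until
all raked margins match within tolerance.  Weights are normalized to sum
to the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class RakingError(RuntimeError):
    pass


@dataclass(frozen=True)
class WeightVector:
    """Positive per-respondent weights, normalized to sum to n."""

    respondent: np.ndarray
    weights: np.ndarray
    variables: tuple[str, ...] = ()
    iterations: int = 0
    max_deviation: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if (w <= 0).any():
            raise ValueError("all raked weights must be positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "respondent", np.asarray(self.respondent))

    @property
    def n(self) -> int:
        return len(self.weights)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=pd.Index(self.respondent, name="respondent"),
                         name="weight")

    def to_frame(self) -> pd.DataFrame:
        return self.as_series().reset_index()


def _margin_table(profiles: pd.DataFrame, var: str,
                  weights: np.ndarray | None = None) -> pd.Series:
    w = np.ones(len(profiles)) if weights is None else weights
    return pd.Series(w).groupby(profiles[var].to_numpy()).sum() / w.sum()


def assess_representativeness(
    profiles: pd.DataFrame,
    targets: dict,
    *,
    threshold: float = 0.02,
) -> pd.DataFrame:
    """Compare sample margins against population targets, one row per variable.

    Reports each variable's maximum absolute deviation (sample proportion
    minus target), a goodness-of-fit chi-square statistic with expected
    counts from the targets, its p-value, and a flag raised when the
    maximum deviation reaches ``threshold`` (default: the 2-percentage-point
    rule used to choose raking variables).
    """
    n = len(profiles)
    rows = []
    for var, spec in targets["variables"].items():
        if var not in profiles.columns:
            continue
        target = spec["population"]
        observed_levels = set(profiles[var].unique())
        unknown = observed_levels - set(target)
        if unknown:
            raise ValueError(f"{var}: sample levels {sorted(unknown)} not in targets")
        obs_prop = _margin_table(profiles, var)
        levels = list(target)
        obs = np.array([obs_prop.get(l, 0.0) * n for l in levels])
        exp = np.array([target[l] * n for l in levels])
        keep = exp > 0
        chi2 = float((((obs - exp) ** 2)[keep] / exp[keep]).sum())
        df = int(keep.sum()) - 1
        max_dev = float(np.max(np.abs(obs / n - exp / n)))
        rows.append({
            "variable": var,
            "max_abs_deviation": max_dev,
            "chi2": chi2,
            "df": df,
            "p_value": float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan,
            "flagged": max_dev >= threshold,
        })
    return pd.DataFrame(rows).set_index("variable")


def rake(
    profiles: pd.DataFrame,
    targets: dict,
    variables: list[str],
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    cap: float | None = None,
    initial: np.ndarray | None = None,
) -> WeightVector:
    """Iterative proportional fitting of respondent weights to population margins.

    Raking on a single variable reduces exactly to post-stratification
    (weight = target share / sample share of the respondent's level).  With
    several variables the margin adjustments cycle until every raked
    variable's weighted margins match the targets within ``tol``.

    ``cap``, if given, clips weights above the cap after each cycle (no
    trimming by default).  Raises ``RakingError`` on non-convergence or
    when a level with positive target mass has no sample members.
    """
    if not variables:
        raise ValueError("no variables to rake on")
    n = len(profiles)
    w = np.ones(n) if initial is None else np.asarray(initial, float).copy()
    if (w <= 0).any():
        raise ValueError("initial weights must be positive")
    level_codes = {}
    target_arrays = {}
    for var in variables:
        target = targets["variables"][var]["population"]
        observed = profiles[var].to_numpy()
        for lvl, t in target.items():
            if t > 0 and not (observed == lvl).any():
                raise RakingError(
                    f"{var}: level {lvl!r} has target {t:.3f} but no sample members"
                )
        unknown = set(observed) - set(target)
        if unknown:
            raise ValueError(f"{var}: sample levels {sorted(unknown)} not in targets")
        codes, uniques = pd.factorize(observed)
        # zero-target empty levels drop out; renormalize so observed levels
        # carry the full target mass
        target_arrays[var] = np.array([target[u] for u in uniques])
        target_arrays[var] /= target_arrays[var].sum()
        level_codes[var] = codes

    max_dev = np.inf
    for it in range(1, max_iter + 1):
        for var in variables:
            codes = level_codes[var]
            t = target_arrays[var]
            observed_mass = np.bincount(codes, weights=w, minlength=len(t)) / w.sum()
            ratio = t / observed_mass
            w = w * ratio[codes]
        if cap is not None:
            w = np.minimum(w, cap)
        w = w / w.sum() * n
        max_dev = 0.0
        for var in variables:
            codes = level_codes[var]
            t = target_arrays[var]
            m = np.bincount(codes, weights=w, minlength=len(t)) / w.sum()
            max_dev = max(max_dev, float(np.max(np.abs(m - t))))
        if max_dev < tol:
            return WeightVector(
                respondent=profiles["respondent"].to_numpy(),
                weights=w, variables=tuple(variables),
                iterations=it, max_deviation=max_dev,
            )
    raise RakingError(
        f"raking did not converge in {max_iter} iterations "
        f"(last max margin deviation {max_dev:.2e})"
    )


def weighted_margins(profiles: pd.DataFrame, weights: WeightVector,
                     variables: list[str]) -> dict[str, dict[str, float]]:
    """Weighted marginal proportions (raked and non-raked variables alike)."""
    w = weights.as_series().reindex(profiles["respondent"]).to_numpy()
    return {
        var: _margin_table(profiles, var, w).to_dict() for var in variables
    }
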