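"""FACT-8D descriptive system: health states, FACT-G item mapping, utility scoring.

The FACT-8D classifies health on eight dimensions (pain, fatigue, nausea,
sleep, work, support, sadness, worry), each on five severity levels
(1 = "not at all" … 5 = "very much" of a problem).  A value set assigns a
utility decrement ``w[d][l]`` to each dimension/level; the utility of a
state is ``1 - sum_d w[d, l(d)]``, anchored so that full health (all level
1) scores 1 and dead scores 0.  States worse than dead score below 0.

Nine FACT-G items map onto the eight dimensions.  Five items are
negatively phrased (a higher item score means a worse problem) and map as
``level = score + 1``; two are positively phrased (sleeping well, able to
work) and are reverse-scored as ``level = 5 - score``; the support
dimension takes the better of its two items, ``level = 5 - max(GS2, GS3)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical dimension order; constant across every table and design.
DIMENSIONS: tuple[str, ...] = (
    "pain", "fatigue", "nausea", "sleep", "work", "support", "sadness", "worry",
)

#: FACT-G items feeding the classifier, in reporting order.
FACTG_ITEMS: tuple[str, ...] = (
    "GP1", "GP2", "GP4", "GF1", "GF5", "GS2", "GS3", "GE1", "GE6",
)

# Dimension -> contributing item(s).  Negatively phrased items map
# level = score + 1; positively phrased (reverse-scored) map 5 - score.
_NEGATIVE_ITEMS = {"pain": "GP4", "fatigue": "GP1", "nausea": "GP2",
                   "sadness": "GE1", "worry": "GE6"}
_POSITIVE_ITEMS = {"sleep": "GF5", "work": "GF1"}
_SUPPORT_ITEMS = ("GS2", "GS3")

N_LEVELS = 5


class ScoringError(ValueError):
    """Raised when FACT-G responses cannot be scored under the active policy."""


@dataclass(frozen=True)
class HealthState:
    """One FACT-8D health state: a severity level 1..5 per dimension."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(DIMENSIONS):
            raise ValueError(
                f"a health state needs {len(DIMENSIONS)} dimension levels, "
                f"got {len(self.levels)}"
            )
        for dim, lev in zip(DIMENSIONS, self.levels):
            if not (isinstance(lev, (int, np.integer)) and 1 <= lev <= N_LEVELS):
                raise ValueError(f"{dim} level must be an integer in 1..5, got {lev!r}")

    @classmethod
    def from_mapping(cls, levels: Mapping[str, int]) -> "HealthState":
        missing = [d for d in DIMENSIONS if d not in levels]
        if missing:
            raise ValueError(f"missing dimension levels: {missing}")
        return cls(tuple(int(levels[d]) for d in DIMENSIONS))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(DIMENSIONS, self.levels))

    def level(self, dimension: str) -> int:
        return self.levels[DIMENSIONS.index(dimension)]


BEST_STATE = HealthState((1,) * 8)
WORST_STATE = HealthState((5,) * 8)


@dataclass(frozen=True)
class ValueSet:
    """Per-dimension, per-level utility decrements.

    ``decrements[d]`` is a length-5 array of non-negative decrement
    magnitudes for levels 1..5 of dimension ``d``; level 1 is always 0.
    ``monotone`` records whether decrements are non-decreasing in severity
    within every dimension (value sets straight from an unconstrained fit
    may violate this; the flag is informational, not an error).
    """

    decrements: dict[str, np.ndarray]
    label: str = ""
    country: str = ""
    source_model: str = ""
    notes: str = ""
    monotone: bool = field(init=False)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise ValueError(f"value set is missing dimension {dim!r}")
            w = np.asarray(self.decrements[dim], dtype=float)
            if w.shape != (N_LEVELS,):
                raise ValueError(f"{dim}: expected 5 level decrements, got shape {w.shape}")
            if w[0] != 0.0:
                raise ValueError(f"{dim}: level-1 decrement must be 0, got {w[0]}")
            if (w < 0).any():
                raise ValueError(f"{dim}: decrements must be non-negative magnitudes")
            clean[dim] = w
        object.__setattr__(self, "decrements", clean)
        mono = all(np.all(np.diff(clean[d]) >= 0) for d in DIMENSIONS)
        object.__setattr__(self, "monotone", bool(mono))

    # -- serialization -------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "ValueSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            decrements={d: np.asarray(v, float) for d, v in payload["dimensions"].items()},
            label=payload.get("label", ""),
            country=payload.get("country", ""),
            source_model=payload.get("source_model", ""),
            notes=payload.get("notes", ""),
        )

    def to_json(self, path: str | Path, *, round_dp: int | None = 3) -> None:
        dims = {
            d: [round(float(x), round_dp) + 0.0 if round_dp is not None else float(x)
                for x in self.decrements[d]]
            for d in DIMENSIONS
        }
        payload = {
            "label": self.label,
            "country": self.country,
            "source_model": self.source_model,
            "notes": self.notes,
            "dimensions": dims,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_frame(self, *, round_dp: int | None = 3) -> pd.DataFrame:
        """Decrement table, dimensions × levels (CSV export mirror)."""
        rows = {d: self.decrements[d] for d in DIMENSIONS}
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"level_{l}" for l in range(1, 6)]
        )
        df.index.name = "dimension"
        return df.round(round_dp) + 0.0 if round_dp is not None else df

    # -- scoring -------------------------------------------------------

    def decrement(self, dimension: str, level: int) -> float:
        return float(self.decrements[dimension][level - 1])

    def as_matrix(self) -> np.ndarray:
        """(8, 5) decrement matrix in canonical dimension order."""
        return np.vstack([self.decrements[d] for d in DIMENSIONS])


def canadian_value_set() -> ValueSet:
    """The packaged Canadian FACT-8D value set (published decrements, verbatim)."""
    return ValueSet.from_json(Path(__file__).parent / "data" / "canada_value_set.json")


def map_factg_to_state(
    responses: Mapping[str, int | None],
    *,
    support_rule: str = "better",
    missing_policy: str = "strict",
) -> HealthState:
    """Map one individual's nine FACT-G item scores to a FACT-8D state.

    Parameters
    ----------
    responses
        Item scores keyed by FACT-G item id (GP1, GP2, GP4, GF1, GF5,
        GS2, GS3, GE1, GE6), each an integer 0–4 or None/NaN for missing.
    support_rule
        Only ``"better"`` is defined: the support level comes from the
        better (higher-scored) of GS2 and GS3.
    missing_policy
        ``"strict"`` refuses to score when any item is missing, naming the
        offending item.  No imputation is offered.
    """
    if support_rule != "better":
        raise ValueError(f"unknown support rule {support_rule!r}")
    if missing_policy != "strict":
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    scores: dict[str, int] = {}
    for item in FACTG_ITEMS:
        raw = responses.get(item)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            raise ScoringError(f"item {item} is missing and the policy is strict")
        val = int(raw)
        if val != raw or not 0 <= val <= 4:
            raise ScoringError(f"item {item} score must be an integer 0..4, got {raw!r}")
        scores[item] = val

    levels: dict[str, int] = {}
    for dim, item in _NEGATIVE_ITEMS.items():
        levels[dim] = scores[item] + 1
    for dim, item in _POSITIVE_ITEMS.items():
        levels[dim] = 5 - scores[item]
    levels["support"] = 5 - max(scores[s] for s in _SUPPORT_ITEMS)
    return HealthState.from_mapping(levels)


def score_state(state: HealthState, valueset: ValueSet) -> float:
    """Utility of a health state: ``1 - sum of its dimension-level decrements``."""
    return 1.0 - float(
        sum(valueset.decrement(d, l) for d, l in zip(DIMENSIONS, state.levels))
    )


def score_factg(
    responses: Mapping[str, int | None],
    valueset: ValueSet,
    **mapping_kwargs,
) -> float:
    """Score FACT-G item responses straight to a utility."""
    return score_state(map_factg_to_state(responses, **mapping_kwargs), valueset)


def pits(valueset: ValueSet) -> float:
    """Utility of the PITS state: the worst state the instrument can describe.

    For a monotone value set this is the all-level-5 state; in general it is
    ``1 - sum_d max_l w[d, l]``, which can be negative (worse than dead).
    """
    return 1.0 - float(sum(valueset.decrements[d].max() for d in DIMENSIONS))


def enumerate_utilities(valueset: ValueSet) -> np.ndarray:
    """Utilities of all 5^8 describable states as an 8-dimensional array.

    ``out[i0, ..., i7]`` is the utility of the state with level ``i0 + 1``
    on the first canonical dimension, etc.  Used for exhaustive range and
    monotonicity audits (390,625 states fit comfortably in memory).
    """
    w = valueset.as_matrix()
    total = np.zeros((N_LEVELS,) * len(DIMENSIONS))
    for axis in range(len(DIMENSIONS)):
        shape = [1] * len(DIMENSIONS)
        shape[axis] = N_LEVELS
        total = total + w[axis].reshape(shape)
    return 1.0 - total


def score_factg_frame(
    frame: pd.DataFrame, valueset: ValueSet
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Score a CSV-shaped frame of FACT-G responses (one row per individual).

    Returns the frame with a ``utility`` column appended, plus a list of
    (row index, message) for rows that could not be scored; those rows get
    NaN utility rather than aborting the batch.
    """
    missing_cols = [c for c in FACTG_ITEMS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"responses file is missing item columns: {missing_cols}")
    out = frame.copy()
    utilities = np.full(len(frame), np.nan)
    errors: list[tuple[int, str]] = []
    for pos, (idx, row) in enumerate(frame.iterrows()):
        resp = {item: (None if pd.isna(row[item]) else row[item]) for item in FACTG_ITEMS}
        try:
            utilities[pos] = score_factg(resp, valueset)
        except ScoringError as exc:
            errors.append((idx, str(exc)))
    out["utility"] = utilities
    return out, errors
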