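"""Partial-profile DCE design: 16 binary choice sets over 8 dimensions + duration.

Each choice set pairs two alternatives ("Situation A" / "Situation B"),
each a FACT-8D health state lived for a stated survival duration drawn
from {1, 2, 5, 10} years.  To limit cognitive load only five of the nine
attributes differ within a set (by default duration plus four dimensions);
the differing attributes are the ones a survey would highlight.  The
attribute display order is fixed across respondents.

The original study's design matrix is unpublished, so `generate_design`
builds a level-balanced randomized design satisfying the same structural
constraints: the best of `n_candidates` random blocks by a level-balance
score (sum over attributes of squared deviations of level frequencies from
uniform).  Externally supplied designs load via `load_design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptive import DIMENSIONS, N_LEVELS, HealthState

DURATION_LEVELS: tuple[int, ...] = (1, 2, 5, 10)
ATTRIBUTES: tuple[str, ...] = DIMENSIONS + ("duration",)
SETS_PER_BLOCK = 16
N_DIFFERING = 5


@dataclass(frozen=True)
class Alternative:
    state: HealthState
    duration: int

    def __post_init__(self) -> None:
        if self.duration not in DURATION_LEVELS:
            raise ValueError(
                f"duration must be one of {DURATION_LEVELS}, got {self.duration}"
            )

    def attribute(self, name: str) -> int:
        return self.duration if name == "duration" else self.state.level(name)


@dataclass(frozen=True)
class ChoiceSet:
    block: int
    set_id: int
    alt_a: Alternative
    alt_b: Alternative
    swapped: bool = False  # True when A/B presentation was flipped post-generation

    @property
    def differing(self) -> tuple[str, ...]:
        """Attributes that differ between the alternatives (highlighted ones)."""
        return tuple(
            a for a in ATTRIBUTES if self.alt_a.attribute(a) != self.alt_b.attribute(a)
        )

    def highlight_flags(self) -> dict[str, bool]:
        diff = set(self.differing)
        return {a: a in diff for a in ATTRIBUTES}

    def swap(self) -> "ChoiceSet":
        return replace(self, alt_a=self.alt_b, alt_b=self.alt_a,
                       swapped=not self.swapped)


@dataclass(frozen=True)
class Design:
    blocks: tuple[tuple[ChoiceSet, ...], ...]
    seed: int | None = None
    balance_score: float = field(default=float("nan"))

    @property
    def sets(self) -> list[ChoiceSet]:
        return [cs for block in self.blocks for cs in block]

    def to_frame(self) -> pd.DataFrame:
        """Long CSV layout: one row per set × alternative."""
        rows = []
        for cs in self.sets:
            for alt_label, alt in (("A", cs.alt_a), ("B", cs.alt_b)):
                row = {"block": cs.block, "set": cs.set_id, "alt": alt_label,
                       "duration": alt.duration}
                row.update(alt.state.as_dict())
                rows.append(row)
        return pd.DataFrame(rows)


def _balance_score(block: list[ChoiceSet]) -> float:
    """Sum over attributes of squared deviation of level counts from uniform."""
    score = 0.0
    for attr in ATTRIBUTES:
        levels = DURATION_LEVELS if attr == "duration" else tuple(range(1, N_LEVELS + 1))
        values = [alt.attribute(attr) for cs in block for alt in (cs.alt_a, cs.alt_b)]
        counts = np.array([values.count(l) for l in levels], float)
        score += float(((counts - counts.mean()) ** 2).sum())
    return score


def _random_set(rng: np.random.Generator, block: int, set_id: int,
                require_duration_differs: bool, n_differing: int) -> ChoiceSet:
    if require_duration_differs:
        dims_diff = rng.choice(len(DIMENSIONS), size=n_differing - 1, replace=False)
        dur_a, dur_b = rng.choice(DURATION_LEVELS, size=2, replace=False)
    else:
        chosen = rng.choice(len(ATTRIBUTES), size=n_differing, replace=False)
        if len(ATTRIBUTES) - 1 in chosen:  # duration drawn as a differing attribute
            dims_diff = chosen[chosen != len(ATTRIBUTES) - 1]
            dur_a, dur_b = rng.choice(DURATION_LEVELS, size=2, replace=False)
        else:
            dims_diff = chosen
            dur_a = dur_b = int(rng.choice(DURATION_LEVELS))
    diff_set = set(int(d) for d in dims_diff)

    levels_a, levels_b = [], []
    for d in range(len(DIMENSIONS)):
        if d in diff_set:
            la, lb = rng.choice(np.arange(1, N_LEVELS + 1), size=2, replace=False)
        else:
            la = lb = int(rng.integers(1, N_LEVELS + 1))
        levels_a.append(int(la))
        levels_b.append(int(lb))
    return ChoiceSet(
        block=block, set_id=set_id,
        alt_a=Alternative(HealthState(tuple(levels_a)), int(dur_a)),
        alt_b=Alternative(HealthState(tuple(levels_b)), int(dur_b)),
    )


def generate_design(
    n_blocks: int = 1,
    seed: int = 0,
    *,
    require_duration_differs: bool = True,
    n_differing: int = N_DIFFERING,
    sets_per_block: int = SETS_PER_BLOCK,
    n_candidates: int = 30,
) -> Design:
    """Generate a level-balanced partial-profile design.

    For each block, `n_candidates` random candidate blocks are drawn and the
    one with the lowest level-imbalance score kept.  Deterministic for a
    fixed seed.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if not 2 <= n_differing <= len(ATTRIBUTES):
        raise ValueError(
            f"n_differing must be between 2 and {len(ATTRIBUTES)}, got {n_differing}"
        )
    rng = np.random.default_rng(seed)
    blocks: list[tuple[ChoiceSet, ...]] = []
    total_score = 0.0
    for b in range(n_blocks):
        best: list[ChoiceSet] | None = None
        best_score = np.inf
        for _ in range(n_candidates):
            cand = [
                _random_set(rng, b, s, require_duration_differs, n_differing)
                for s in range(sets_per_block)
            ]
            sc = _balance_score(cand)
            if sc < best_score:
                best, best_score = cand, sc
        blocks.append(tuple(best))  # type: ignore[arg-type]
        total_score += best_score
    return Design(tuple(blocks), seed=seed, balance_score=total_score)


def validate_design(design: Design, *, n_differing: int = N_DIFFERING) -> dict:
    """Structural audit: differing-attribute counts, level usage, violations.

    Violations are reported, never raised — a design with problems is still
    inspectable.
    """
    violations: list[str] = []
    diff_counts: dict[tuple[int, int], int] = {}
    level_freq = {a: {} for a in ATTRIBUTES}
    for cs in design.sets:
        ndiff = len(cs.differing)
        diff_counts[(cs.block, cs.set_id)] = ndiff
        if ndiff != n_differing:
            violations.append(
                f"block {cs.block} set {cs.set_id}: {ndiff} attributes differ "
                f"(expected {n_differing})"
            )
        for alt in (cs.alt_a, cs.alt_b):
            if alt.duration not in DURATION_LEVELS:
                violations.append(
                    f"block {cs.block} set {cs.set_id}: duration {alt.duration} "
                    f"not in {DURATION_LEVELS}"
                )
            for attr in ATTRIBUTES:
                v = alt.attribute(attr)
                level_freq[attr][v] = level_freq[attr].get(v, 0) + 1
    for block in design.blocks:
        if len(block) != SETS_PER_BLOCK:
            violations.append(f"block {block[0].block if block else '?'} has "
                              f"{len(block)} sets (expected {SETS_PER_BLOCK})")
    return {
        "n_sets": len(design.sets),
        "differing_counts": diff_counts,
        "level_frequencies": level_freq,
        "duration_usage": level_freq["duration"],
        "violations": violations,
        "ok": not violations,
    }


def randomize_presentation(design: Design, seed: int) -> Design:
    """Flip A/B presentation of each set with probability 1/2 (attribute order fixed).

    Choice probabilities are invariant up to relabeling, so estimation does
    not depend on this step; it exists to emulate the survey presentation.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for block in design.blocks:
        flips = rng.random(len(block)) < 0.5
        blocks.append(tuple(cs.swap() if f else cs for cs, f in zip(block, flips)))
    return Design(tuple(blocks), seed=design.seed, balance_score=design.balance_score)


def load_design(path: str | Path) -> Design:
    """Load an externally supplied design CSV (long layout, see `Design.to_frame`)."""
    df = pd.read_csv(path)
    required = {"block", "set", "alt", "duration", *DIMENSIONS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file is missing columns: {sorted(missing)}")
    blocks: dict[int, dict[int, dict[str, Alternative]]] = {}
    for _, row in df.iterrows():
        alt = Alternative(
            HealthState(tuple(int(row[d]) for d in DIMENSIONS)), int(row["duration"])
        )
        blocks.setdefault(int(row["block"]), {}).setdefault(int(row["set"]), {})[
            str(row["alt"])
        ] = alt
    out_blocks = []
    for b in sorted(blocks):
        sets = []
        for s in sorted(blocks[b]):
            pair = blocks[b][s]
            if set(pair) != {"A", "B"}:
                raise ValueError(f"block {b} set {s}: need exactly alternatives A and B")
            sets.append(ChoiceSet(block=b, set_id=s, alt_a=pair["A"], alt_b=pair["B"]))
        out_blocks.append(tuple(sets))
    return Design(tuple(out_blocks))
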