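"""Synthetic respondents and random-utility DCE choices.

Respondent demographics mirror the valuation survey's variables: quota
variables (sex, age group, region) are sampled quota-exact against census
margins by largest-remainder rounding; non-quota variables (language,
education, self-rated health) are drawn independently from a deliberately
distorted distribution so the raking stage has real work to do, emulating
the over-representation of English speakers and higher education in the
achieved panel sample.

Choices follow the QALY-consistent random-utility model

    U_isj = alpha * t_isj + sum_dl beta_dl * x_isjdl * t_isj + eps_isj

with i.i.d. type-I extreme-value (Gumbel) errors, so the probability that
respondent i picks alternative A of set s is the logistic function of the
deterministic utility difference.  Gumbel errors are the distribution under
which the conditional logit estimator is the MLE, which is what the
estimation stage fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .descriptive import DIMENSIONS, N_LEVELS
from .design import ChoiceSet, Design

_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class TruePreferences:
    """Generating preferences: utility per life-year and level-by-duration coefficients.

    ``alpha`` is the utility of one life-year in full health; ``beta[d]`` is
    a length-5 array of level-by-duration coefficients for dimension ``d``
    with the level-1 entry fixed at 0.  Under monotone preferences the
    entries are non-increasing (more severe levels more negative).
    """

    alpha: float
    beta: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha (utility per life-year in full health) must be > 0")
        clean = {}
        for d in DIMENSIONS:
            b = np.asarray(self.beta[d], float)
            if b.shape != (N_LEVELS,) or b[0] != 0.0:
                raise ValueError(f"{d}: beta must be 5 levels with level 1 fixed at 0")
            clean[d] = b
        object.__setattr__(self, "beta", clean)

    def deterministic_utility(self, state_levels: Sequence[int], duration: float) -> float:
        dec = sum(self.beta[d][l - 1] for d, l in zip(DIMENSIONS, state_levels))
        return (self.alpha + dec) * duration

    @classmethod
    def from_published(cls, model: str = "model3") -> "TruePreferences":
        """Preferences set to the published conditional-logit estimates."""
        payload = json.loads((_DATA / "conditional_logit_coefficients.json").read_text())
        m = payload[model]
        return cls(alpha=m["alpha"], beta={d: np.asarray(v, float)
                                           for d, v in m["beta"].items()})


# ---------------------------------------------------------------------------
# demographics


def load_margin_targets(path: str | Path | None = None) -> dict:
    """Load margin targets (population + sample distributions) from JSON.

    Proportions are renormalized per variable: printed census margins are
    rounded and (for region, education) do not sum exactly to 1.
    """
    payload = json.loads(Path(path or _DATA / "canada_margins.json").read_text())
    for var, spec in payload["variables"].items():
        for key in ("population", "sample"):
            probs = spec[key]
            total = sum(probs.values())
            if total <= 0:
                raise ValueError(f"{var}.{key}: proportions sum to {total}")
            spec[key] = {lvl: p / total for lvl, p in probs.items()}
    return payload


def _largest_remainder_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to probs (largest remainder)."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _skewed_distribution(target: dict[str, float],
                         skew: Mapping[str, float]) -> dict[str, float]:
    """Target distribution with additive distortions; others rescaled to sum 1."""
    probs = dict(target)
    bumped = set(skew)
    for lvl, delta in skew.items():
        if lvl not in probs:
            raise ValueError(f"skew names unknown level {lvl!r}")
        probs[lvl] = max(probs[lvl] + delta, 0.0)
    rest = [l for l in probs if l not in bumped]
    rest_total = sum(probs[l] for l in rest)
    residual = 1.0 - sum(probs[l] for l in bumped)
    if residual < 0 or (rest and rest_total == 0):
        raise ValueError("skew leaves no probability mass for remaining levels")
    for l in rest:
        probs[l] = probs[l] / rest_total * residual if rest_total else 0.0
    return probs


def simulate_respondents(
    margins: dict,
    n: int = 1582,
    *,
    skew: Mapping[str, Mapping[str, float]] | str | None = "study",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic cohort of ``n`` respondent profiles.

    Quota variables are quota-exact (largest-remainder) against the
    population margins; the other variables are independent categorical
    draws.  ``skew`` controls how the non-quota draws deviate from the
    population: the default ``"study"`` uses the achieved study-sample
    proportions packaged with the margins; a mapping
    ``{variable: {level: +delta}}`` applies additive distortions; ``None``
    draws at the population margins (a representative sample).
    """
    rng = np.random.default_rng(seed)
    quota_vars = margins["quota_variables"]
    skewed_vars = margins["skewed_variables"]
    if n < max(len(margins["variables"][v]["population"]) for v in quota_vars):
        raise ValueError("n is smaller than the number of quota cells")

    out = {"respondent": np.arange(1, n + 1)}
    for var in quota_vars:
        target = margins["variables"][var]["population"]
        levels = list(target)
        counts = _largest_remainder_counts(np.array([target[l] for l in levels]), n)
        column = np.repeat(levels, counts)
        rng.shuffle(column)
        out[var] = column
    for var in skewed_vars:
        spec = margins["variables"][var]
        if skew == "study":
            dist = spec["sample"]
        elif skew is None:
            dist = spec["population"]
        else:
            dist = _skewed_distribution(spec["population"], skew.get(var, {}))
        levels = list(dist)
        out[var] = rng.choice(levels, size=n, p=[dist[l] for l in levels])
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# choices


def choice_probability(prefs: TruePreferences, choice_set: ChoiceSet) -> float:
    """Closed-form probability that alternative A of the set is chosen."""
    va = prefs.deterministic_utility(choice_set.alt_a.state.levels,
                                     choice_set.alt_a.duration)
    vb = prefs.deterministic_utility(choice_set.alt_b.state.levels,
                                     choice_set.alt_b.duration)
    return float(expit(va - vb))


def simulate_choices(
    design: Design,
    prefs: TruePreferences,
    profiles: pd.DataFrame,
    *,
    seed: int = 0,
    partial_completion_rate: float = 81 / 1582,
    randomize_ab: bool = True,
) -> pd.DataFrame:
    """Simulate each respondent's Bernoulli choices over their block of sets.

    Respondents cycle over the design's blocks.  With probability
    ``partial_completion_rate`` a respondent abandons the survey partway
    through, completing a uniform 1..15 of the 16 sets (every simulated
    respondent completes at least one set, matching the analysis-set
    inclusion rule).  ``randomize_ab`` flips A/B presentation per
    respondent × set; the chosen flag always refers to the presented A/B.

    Returns the long-format choice dataset: two rows (A and B) per answered
    set, with exactly one ``chosen`` flag per pair.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_blocks = len(design.blocks)
    for i, rid in enumerate(profiles["respondent"].to_numpy()):
        block = design.blocks[i % n_blocks]
        n_sets = len(block)
        if partial_completion_rate and rng.random() < partial_completion_rate:
            n_sets = int(rng.integers(1, len(block)))
        for cs in block[:n_sets]:
            presented = cs.swap() if (randomize_ab and rng.random() < 0.5) else cs
            p_a = choice_probability(prefs, presented)
            a_chosen = rng.random() < p_a
            for alt_label, alt, chosen in (
                ("A", presented.alt_a, a_chosen),
                ("B", presented.alt_b, not a_chosen),
            ):
                row = {"respondent": rid, "set": cs.set_id, "alt": alt_label,
                       "chosen": int(chosen), "duration": alt.duration}
                row.update(alt.state.as_dict())
                rows.append(row)
    return pd.DataFrame(rows)


def validate_choice_dataset(choices: pd.DataFrame) -> None:
    """Check the long-format invariants: paired alternatives, one choice per set."""
    required = {"respondent", "set", "alt", "chosen", "duration", *DIMENSIONS}
    missing = required - set(choices.columns)
    if missing:
        raise ValueError(f"choice dataset is missing columns: {sorted(missing)}")
    grouped = choices.groupby(["respondent", "set"])
    sizes = grouped.size()
    if not (sizes == 2).all():
        bad = sizes[sizes != 2].index[:5].tolist()
        raise ValueError(f"each (respondent, set) needs exactly 2 alternatives; bad: {bad}")
    chosen = grouped["chosen"].sum()
    if not (chosen == 1).all():
        bad = chosen[chosen != 1].index[:5].tolist()
        raise ValueError(f"each (respondent, set) needs exactly 1 chosen row; bad: {bad}")
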