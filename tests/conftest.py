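import numpy as np
import pandas as pd
import pytest

from fact8d import (
    ModelSpec,
    TruePreferences,
    canadian_value_set,
    generate_design,
    load_margin_targets,
    simulate_choices,
    simulate_respondents,
)

ALL_BEST_RESPONSES = {"GP1": 0, "GP2": 0, "GP4": 0, "GF1": 4, "GF5": 4,
                      "GS2": 4, "GS3": 4, "GE1": 0, "GE6": 0}
ALL_WORST_RESPONSES = {"GP1": 4, "GP2": 4, "GP4": 4, "GF1": 0, "GF5": 0,
                       "GS2": 0, "GS3": 0, "GE1": 4, "GE6": 4}


@pytest.fixture(scope="session")
def canadian():
    return canadian_value_set()


@pytest.fixture(scope="session")
def margins():
    return load_margin_targets()


@pytest.fixture(scope="session")
def sim():
    """A moderate simulated study reused across estimation tests.

    400 respondents over 12 blocks of 16 sets, choices generated under the
    published constrained coefficients; large enough to identify all 33
    parameters, small enough to fit in well under a second.
    """
    margins = load_margin_targets()
    design = generate_design(12, seed=101)
    profiles = simulate_respondents(margins, 400, seed=102)
    prefs = TruePreferences.from_published("model3")
    choices = simulate_choices(design, prefs, profiles, seed=103,
                               partial_completion_rate=0.0)
    return {"design": design, "profiles": profiles, "prefs": prefs,
            "choices": choices, "margins": margins}


@pytest.fixture(scope="session")
def full_spec():
    return ModelSpec.full()


def make_profiles(levels_per_var: dict[str, list], counts: dict[str, list[int]]):
    """Construct an exact-count profile frame for weighting tests."""
    cols = {}
    n = sum(counts[next(iter(counts))])
    for var, levels in levels_per_var.items():
        col = np.repeat(levels, counts[var])
        assert len(col) == n
        cols[var] = col
    cols["respondent"] = np.arange(1, n + 1)
    return pd.DataFrame(cols)
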