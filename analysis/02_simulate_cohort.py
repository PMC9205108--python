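#!/usr/bin/env python
"""Simulate the survey: 1,582 respondents with study-like demographic skew,
each answering one 16-set block under the published constrained preferences.

Quota variables (sex, age, region) match census margins exactly; language,
education and self-rated health are drawn at the achieved study-sample
proportions so the weighting stage has real distortion to correct.
"""

import argparse
from pathlib import Path

from fact8d import (
    TruePreferences,
    load_design,
    load_margin_targets,
    simulate_choices,
    simulate_respondents,
    validate_choice_dataset,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--n", type=int, default=1582)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    margins = load_margin_targets()
    design = load_design(args.results / "design.csv")
    profiles = simulate_respondents(margins, args.n, skew="study", seed=args.seed)
    prefs = TruePreferences.from_published("model3")
    choices = simulate_choices(design, prefs, profiles, seed=args.seed + 1)
    validate_choice_dataset(choices)

    profiles.to_csv(args.results / "profiles.csv", index=False)
    choices.to_csv(args.results / "choices.csv", index=False)
    n_complete = (choices.groupby("respondent")["set"].nunique() == 16).sum()
    print(f"cohort: {len(profiles)} respondents "
          f"({n_complete} completed all 16 sets), "
          f"{len(choices) // 2} choice-set observations")
    print(f"-> {args.results / 'profiles.csv'}, {args.results / 'choices.csv'}")


if __name__ == "__main__":
    main()
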