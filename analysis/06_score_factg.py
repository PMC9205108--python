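#!/usr/bin/env python
"""Score FACT-G responses to utilities with the packaged Canadian value set.

Builds a small demonstration response sheet (best, intermediate, and worst
profiles), scores it, and reports the utilities.  Point --responses at a
real FACT-G CSV (columns GP1, GP2, GP4, GF1, GF5, GS2, GS3, GE1, GE6,
scores 0-4) to score it instead.
"""

import argparse
from pathlib import Path

import pandas as pd

from fact8d import FACTG_ITEMS, score_command


def demo_frame() -> pd.DataFrame:
    positive = {"GF1", "GF5", "GS2", "GS3"}
    best = {i: (4 if i in positive else 0) for i in FACTG_ITEMS}
    worst = {i: 4 - v for i, v in best.items()}
    mild = dict(best, GP4=1, GP1=1, GF5=3)
    moderate = dict(best, GP4=2, GP1=2, GP2=1, GE1=2, GE6=2)
    return pd.DataFrame([best, mild, moderate, worst],
                        index=["best", "mild", "moderate", "worst"])


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    ap.add_argument("--responses", type=Path, default=None,
                    help="FACT-G responses CSV; defaults to a built-in demo sheet.")
    ap.add_argument("--valueset", type=Path, default=None,
                    help="Value-set JSON; defaults to the packaged Canadian set.")
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    responses = args.responses
    if responses is None:
        responses = args.results / "factg_demo_responses.csv"
        demo_frame().to_csv(responses, index=False)

    out = args.results / "factg_utilities.csv"
    summary = score_command(responses, args.valueset, out)
    scored = pd.read_csv(out)
    print(scored.to_string(index=False))
    print(f"\nscored {summary['n_scored']}/{summary['n']} rows; "
          f"utility range [{summary['utility_min']:.3f}, {summary['utility_max']:.3f}], "
          f"mean {summary['utility_mean']:.3f} -> {out}")
    if summary["errors"]:
        print(f"rows with errors: {summary['errors']}")


if __name__ == "__main__":
    main()
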