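#!/usr/bin/env python
"""Check sample representativeness and derive raked survey weights.

Variables off their census margin by >= 2 percentage points on any level
are raked (iterative proportional fitting) until the weighted margins match
the population within 1e-6.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from fact8d import assess_representativeness, load_margin_targets, rake
from fact8d.weights import weighted_margins


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    ap.add_argument("--threshold", type=float, default=0.02)
    args = ap.parse_args()

    margins = load_margin_targets()
    profiles = pd.read_csv(args.results / "profiles.csv")
    report = assess_representativeness(profiles, margins, threshold=args.threshold)
    report.reset_index().to_csv(args.results / "representativeness.csv", index=False)
    print(report.round(4).to_string())

    flagged = list(report.index[report["flagged"]])
    print(f"\nflagged at the {args.threshold:.0%} rule: {flagged}")
    weights = rake(profiles, margins, flagged)
    weights.to_frame().to_csv(args.results / "weights.csv", index=False)
    post = weighted_margins(profiles, weights, flagged)
    (args.results / "weighted_margins.json").write_text(
        json.dumps(post, indent=2) + "\n")
    print(f"raked in {weights.iterations} iterations; "
          f"max weighted-margin deviation {weights.max_deviation:.2e}; "
          f"weight range [{weights.weights.min():.3f}, {weights.weights.max():.3f}]")


if __name__ == "__main__":
    main()
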