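#!/usr/bin/env python
"""Summarise the cohort analysis into a markdown report.

Builds results/cohort_analysis/report.md from the exported tables and
prints the modulation-index summary per tracker and the cross-tracker
sign agreement it found.
"""

import argparse
from pathlib import Path

import pandas as pd

from cogvergence import run_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results" / "cohort_analysis")
    args = ap.parse_args()

    report = run_report(args.results)

    mi = pd.read_csv(args.results / "subject_mi.csv")
    for tracker, sub in mi.groupby("tracker_id"):
        vals = sub.mi.dropna()
        print(f"{tracker}: mi mean {vals.mean():.3f} +- {vals.std(ddof=1):.3f} "
              f"({(vals > 0).mean():.1%} of {len(vals)} subjects positive)")
    quad = pd.read_csv(args.results / "quadrant_counts.csv")
    if len(quad):
        q = quad.iloc[0]
        print(f"positive mi in both trackers: {int(q.both_positive)} subjects; "
              f"{q.tracker_1} only: {int(q.first_only)}, "
              f"{q.tracker_2} only: {int(q.second_only)}, "
              f"neither: {int(q.neither)}")
    print(f"report written to {report}")


if __name__ == "__main__":
    main()
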