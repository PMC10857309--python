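#!/usr/bin/env python
"""Simulate the default oddball cohort.

Writes a 28-subject dataset — each subject recorded by the
infrared-like ("ET") and webcam-like ("WC") tracker against the same
100-trial event log (80 distractor / 20 target) — to scratch/cohort/,
and prints the design counts it produced.
"""

import argparse
from pathlib import Path

from cogvergence import AnalysisConfig, SimulationParams, read_event_log, run_simulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    cfg = AnalysisConfig(seed=args.seed)
    params = SimulationParams(seed=args.seed)
    data = run_simulate(cfg, params, args.out)

    subjects = sorted(p for p in data.iterdir() if p.is_dir())
    logs = [read_event_log(s / "events.csv") for s in subjects]
    print(f"wrote {len(subjects)} subjects x {len(params.trackers)} trackers to {data}")
    print(f"trials per session: {len(logs[0])} "
          f"({logs[0].n_distractors} distractor / {logs[0].n_targets} target)")
    print(f"cohort totals: {sum(l.n_distractors for l in logs)} distractor, "
          f"{sum(l.n_targets for l in logs)} target trials")


if __name__ == "__main__":
    main()
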