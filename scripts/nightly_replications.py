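#!/usr/bin/env python
"""Full-scale replication runs (multi-hour on one CPU; run as nightly jobs).

These execute the reference experiments at the full parameter set
(1000 um cube, 71^3 grid, 20 h cycle, growth from 10 seeder cells) and
print the headline observables of each:

* growth       -- day-14 diameter (~700 um) and the hypoxia (~9.5 d) /
                  central-anoxia (~10 d) / glucose-depletion (~11 d) onsets;
* single_dose  -- 4 Gy at day 14 (O_max 2.9 or 1): anoxic fraction at +4 h,
                  return to pre-treatment oxygenation (~15 h with O_max 2.9),
                  persistence of reoxygenation (~42 h with O_max 1);
* fractionated -- 2 Gy / 24 h or 4 Gy / 48 h schedules; with O_max 1 and
                  4 Gy / 48 h, the fraction index from which no
                  radiobiologically hypoxic cell is present at delivery.

Usage: python scripts/nightly_replications.py growth --seed 1 --out scratch/n1
Run each experiment for >= 3 seeds and compare with +-15% / +-1 d / +-3 h
tolerances as appropriate.
"""

import argparse
import json
from pathlib import Path

from spheroidrt.config import SimulationConfig
from spheroidrt.radiotherapy import TreatmentSchedule
from spheroidrt.runner import run_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("experiment",
                        choices=["growth", "single_dose", "fractionated"])
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--dose", type=float, default=4.0)
    parser.add_argument("--interval", type=float, default=48.0)
    parser.add_argument("--fractions", type=int, default=5)
    parser.add_argument("--omax", type=float, default=None,
                        help="override O_max for the doses (e.g. 1.0)")
    parser.add_argument("--follow-up", type=float, default=48.0)
    parser.add_argument("--out", type=Path, default=Path("scratch/nightly"))
    args = parser.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    schedule = None
    if args.experiment == "single_dose":
        schedule = TreatmentSchedule.fractionated(
            cfg.total_days * 24.0, args.dose, args.interval, 1, o_max=args.omax)
    elif args.experiment == "fractionated":
        schedule = TreatmentSchedule.fractionated(
            cfg.total_days * 24.0, args.dose, args.interval, args.fractions,
            o_max=args.omax)
    summary = run_experiment(args.experiment, cfg, schedule,
                             outdir=args.out / f"{args.experiment}_s{args.seed}",
                             follow_up_h=args.follow_up)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
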