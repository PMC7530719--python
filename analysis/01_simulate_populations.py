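#!/usr/bin/env python
"""Simulate per-cell expression populations and their two-stage response.

Generates the unstimulated setpoint mixture, applies a low (partial) and a
high (maximal) dose of stimulus, and summarizes the ceiling statistics:
the low dose shifts the distribution while respecting the reference
ceiling (Stage I); the high dose drives ~20% of cells through it
(Stage II).  Writes per-cell tables and the two-stage summary.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from mycsetpoint import distributions as dist
from mycsetpoint import simulate


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/01_populations"))
    args = ap.parse_args()
    warnings.simplefilter("ignore")
    args.out.mkdir(parents=True, exist_ok=True)

    base = simulate.simulate_population(simulate.PopulationConfig(seed=args.seed))
    low = simulate.apply_stimulus(base, simulate.LOW_DOSE, seed=args.seed + 1)
    high = simulate.apply_stimulus(base, simulate.HIGH_DOSE, seed=args.seed + 2)
    df = pd.DataFrame(
        {
            "unstimulated": base.cells["observed"],
            "low_dose": low.cells["observed"],
            "high_dose": high.cells["observed"],
            "high_dose_breakthrough": high.cells["breakthrough"],
        }
    )
    df.to_csv(args.out / "per_cell_expression.csv", index=False, float_format="%.6g")

    summary = {}
    for name, treated in [("low_dose", low), ("high_dose", high)]:
        rep = dist.two_stage_report(
            base.cells["observed"], treated.cells["observed"], q=0.99
        )
        summary[name] = {
            "stage": rep.stage,
            "ceiling_AU": rep.ceiling,
            "fraction_above_ceiling": rep.breakthrough_fraction,
            "conditional_p": rep.conditional_p,
            "mean_shift_AU": rep.mean_shift,
            "mode_shift_AU": rep.mode_shift,
        }
        print(
            f"{name}: stage {rep.stage}, "
            f"{100 * rep.breakthrough_fraction:.2f}% above the "
            f"{rep.ceiling:.2f} AU ceiling, mean shift {rep.mean_shift:+.2f} AU"
        )
    (args.out / "two_stage_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
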