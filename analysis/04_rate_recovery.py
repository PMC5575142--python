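#!/usr/bin/env python
"""Parameter-recovery study for the staged-rate fitting pipeline.

Emulates the bench desorption experiment (two-stage first-order decay,
sampled every 2 h to 96 h) and asks whether segmented log-linear regression
recovers the generating rates: exactly on noiseless data, and with small
median error across 200 replicates at 10% multiplicative measurement noise.
Writes results/rate_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import pyrfate as pf

OUT = Path(__file__).resolve().parents[1] / "results"
TRUE_RATES = (0.0775, 0.0051)  # wet-regime desorption stages
BREAK_H = 18.0
GRID = np.arange(0.0, 97.0, 2.0)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=200)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    sched = pf.PiecewiseRateSchedule.from_breakpoints(
        list(TRUE_RATES), [BREAK_H], source="sediment", destination="water"
    )

    clean = pf.generate_decay_series(sched, 100.0, GRID, noise_cv=0.0)
    exact = pf.fit_segmented_rates(clean, max_segments=3)
    print(
        f"noiseless: breakpoint {exact.breakpoints[0]:g} h (true {BREAK_H:g}), "
        f"rates {exact.segment_rates[0]:.6f}/{exact.segment_rates[1]:.6f} "
        f"(true {TRUE_RATES[0]}/{TRUE_RATES[1]})"
    )

    rows = []
    for rep in range(args.replicates):
        seed = args.seed * args.replicates + rep
        series = pf.generate_decay_series(sched, 100.0, GRID, noise_cv=0.10, seed=seed)
        fit = pf.fit_segmented_rates(series, max_segments=2)
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "breakpoint_h": fit.breakpoints[0] if fit.breakpoints else np.nan,
                "rate_early": fit.segment_rates[0],
                "rate_late": fit.segment_rates[-1],
                "rel_err_early": abs(fit.segment_rates[0] - TRUE_RATES[0]) / TRUE_RATES[0],
                "rel_err_late": abs(fit.segment_rates[-1] - TRUE_RATES[1]) / TRUE_RATES[1],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "rate_recovery.csv", index=False)
    med_e, med_l = df["rel_err_early"].median(), df["rel_err_late"].median()
    med_b = df["breakpoint_h"].median()
    print(
        f"{args.replicates} replicates at CV 10%: median relative error "
        f"{med_e:.1%} (early rate) / {med_l:.1%} (late rate); median "
        f"breakpoint {med_b:g} h. Table -> results/rate_recovery.csv"
    )


if __name__ == "__main__":
    main()
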