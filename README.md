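# pyrfate

Seasonal multimedia fate of pyrene with absorbing Markov chains.

Pyrene is a persistent 4-ring polycyclic aromatic hydrocarbon that cycles
between the water column and bed sediment and is ultimately eliminated by
volatilizing to air or being biodegraded by sediment microorganisms.
`pyrfate` models this as a discrete-time absorbing Markov chain over four
states — volatilized (air), biodegraded (sediment microbes), dissolved
(water), sorbed (sediment) — driven by staged laboratory transport and
elimination rates measured under three seasonal moisture regimes (normal
≈ 13 °C, wet ≈ 25 °C, dry ≈ 5 °C). It is aimed at environmental-fate and
ecotoxicology modellers who want transparent, auditable compartment
bookkeeping rather than a black-box fugacity package.

Each hour the state vector `U` is propagated by a row-stochastic
transition matrix rebuilt from the piecewise rates in force at that hour:

    U(t + t0) = U(t) · P(t),        P = [ I  0 ]
                                        [ R  Q ]

With absorbing states ordered first, `Q` holds transient→transient and
`R` transient→absorbing hourly probabilities. Once the rates are past
their last breakpoint the chain is homogeneous, and the fundamental
matrix `N = (I − Q)⁻¹` with `B = N·R` gives the ultimate absorption
split in closed form — an independent cross-check the simulator must
match to 1e-6.

The package also ships a synthetic-experiment module: piecewise
first-order decay curves with lognormal measurement noise, and a
segmented log-linear regression that recovers staged rates (exhaustive
breakpoint search, parsimony-based segment-count selection), emulating
how staged rate tables are distilled from bench kinetics experiments.

## Worked example

```sh
$ pyrfate simulate --regime normal --out runs/normal
trajectory -> runs/normal_trajectory.csv
report     -> runs/normal_report.json
  regime: normal
  threshold: 0.01
  t0: 1.0
  interpretation: probability
  horizon_h: 971.0
  water_elimination_h: 148.0
  sediment_elimination_h: 308.0
  volatilization_pct: 56.03459344170343
  biodegradation_pct: 43.96540655829658
```

Reading the numbers: starting from 102.05 ng/mL-equivalents all in water,
the water column falls below the negligible threshold (1% of initial
total mass) after 148 h and sediment after 308 h; of everything
eliminated, 56% left by volatilization and 44% by in-sediment
biodegradation. The wet regime clears fastest (water 56 h, sediment
140 h, 63% volatilized) and the dry regime slowest (530 h / 863 h, with
volatilization collapsing to 9% because the cold-season volatility rate
is 17× smaller while sediment biodegradation keeps working).

The same numbers come from the library API:

```python
import pyrfate as pf

report, traj = pf.elimination_report(pf.regime_parameters("normal"))
print(report.water_time, report.volatilization_fraction)  # 148.0 56.034...
```

Other subcommands: `pyrfate validate` (outgoing-probability audit of a
rate set), `pyrfate generate` / `pyrfate fit` (synthetic kinetics series
and staged-rate recovery), `pyrfate fractions` (pathway split of a stored
trajectory). Custom systems are plain YAML/JSON configs; the bundled
regimes live in `src/pyrfate/data/*.yaml` in the same schema.

## Analysis scripts

The `analysis/` drivers re-run the full study end to end and write tables
under `results/`:

1. `01_validate_regimes.py` — admissibility audit of the three rate sets.
2. `02_simulate_fate.py` — hourly trajectories and elimination reports.
3. `03_pathway_split.py` — simulated ultimate splits vs the closed-form
   fundamental-matrix route (agreement ~1e-9 pp).
4. `04_rate_recovery.py` — noiseless and noisy (200 × CV 10%)
   staged-rate recovery study.

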