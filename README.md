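# waitsim

Individual-level (microsimulation) model of a procedure waitlist under
risk-based prioritization and a fixed-capacity wait-time budget.

A closed cohort of synthetic patients is sampled with heterogeneous,
right-skewed 12-week predicted risks of death, hospitalization, and
urgent-procedure conversion (one latent severity quantile drives all three
margins comonotonically). Patients are classified into percentile risk
tiers; prioritized tiers get short fixed waits and the non-prioritized tier
absorbs the wait that keeps the size-weighted mean at the budget target
(12.5 weeks by default). Everyone is then followed in weekly cycles under
Weibull time-escalating hazards: waiting patients can die, be hospitalized
(possibly converting to an urgent procedure), or exit electively at their
assigned week. Hazard multipliers are calibrated so the no-prioritization
reference scenario reproduces registry-count targets, and a scenario grid
(tier sizes × tier waits) is swept against the reference with common random
numbers to locate wait-time benchmarks under a cap on the low-risk wait.

## Layout

| Module | Role |
| --- | --- |
| `waitsim.risk_population` | synthetic cohorts: Beta risk margins, latent-severity comonotone sampling, percentile thresholds, cohort CSV I/O |
| `waitsim.prioritization` | tier schemes, percentile classification, budget-constrained wait solving and integer-week assignment |
| `waitsim.hazards` | 12-week risk → Weibull scale conversion, weekly event probabilities, closed-form cumulative-incidence oracles |
| `waitsim.engine` | weekly-cycle closed-cohort simulation, replicate aggregation |
| `waitsim.calibration` | registry-count targets, sequential bisection of the hazard multipliers under common random numbers |
| `waitsim.grid` | scenario-grid enumeration (351 combinations by default), CRN execution, relative risks, benchmark selection |
| `waitsim.reporting` / `waitsim.cli` / `waitsim.config` | heatmap tables, YAML config, command-line surface |

## CLI

One YAML config drives every stage (all blocks optional — defaults are
built in); `--n/--reps/--seed` override the scaling knobs.

```sh
waitsim make-cohort --n 1000 --seed 1 --out cohort.csv
waitsim calibrate --n 10000 --reps 20 --seed 1 --out-dir cal/
waitsim run --params cal/fitted_hazards.yaml --n 10000 --reps 20 --seed 1 --out outcomes.csv
waitsim grid --params cal/fitted_hazards.yaml --n 5000 --reps 10 --seed 1 --out grid_results.csv
waitsim report --grid grid_results.csv --out-dir report/
```

`report` writes one wide CSV per outcome per wait-time panel (rows =
medium-tier size, columns = high-tier size, cells = `value (RR)`), plus the
low-risk wait table; display rounding is 1 dp for percentages and weeks and
2 dp for relative risks, with the raw full-precision table alongside.

## Notes and known discrepancies

- The synthetic risk distribution is an implementation stand-in for an
  unavailable empirical distribution; distribution-dependent results
  (per-scenario outcome levels, relative risks) are validated as
  directional properties, not as point reproductions.
- The budget identity gives a 13.1-week low-risk wait for the 5%/5% scheme
  at 5/9-week waits (sometimes quoted as 14 weeks elsewhere); this package
  implements the identity.
- A literal reading of the scenario axes yields 351 grid combinations
  (6·6·3·3 three-group + 9 equal-thirds + 18 two-group). All axis lists
  are configurable, so alternative grids can be enumerated.
- The hospitalization calibration target derived from registry counts is
  33.9%; a calibrated reference run therefore reports ≈33.9%, not the
  33.4% sometimes printed for the modelled reference.
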