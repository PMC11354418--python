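# cohortdd

Cohort life tables on a degree-day clock for insect mass-rearing trials.

`cohortdd` analyses stage-structured rearing logs of ectotherms — here
calibrated to *Zelus renardii*, the Leafhopper Assassin Bug — where the
natural clock is not calendar time but **accumulated degree-days (ADD)**:
heat units above a developmental threshold (15 °C) summed day by day from
oviposition. The package provides:

- **Degree-day accounting** — the simple-average method
  `max(0, (Tmax + Tmin)/2 − Tbase)` per day, interval accumulation with
  half-open `[entry, exit)` attribution, and per-individual ledgers that
  split an insect's lifetime heat budget by stage.
- **Cohort life tables** — `N, lx, px, qx, dx` from raw survivor counts and
  life expectancy `ex` in ADD, plus the population trend
  `T = eggs in next brood / eggs in previous brood` and its per-diet mean.
- **Comparison statistics** — sex-ratio χ² with a standardized-residual
  post hoc, exact (Freeman–Halton) mortality tests with pairwise Fisher
  tests, Welch ANOVA + Games–Howell on cumulative ADD, Kruskal–Wallis per
  instar, and a two-way fecundity/hatch ANOVA with normality and
  homogeneity diagnostics.
- **A seeded synthetic-cohort generator** — lognormal per-stage heat
  requirements inverted against a temperature series, Bernoulli stage
  mortality, sex assignment and truncated-normal fecundity at emergence —
  so the whole pipeline is testable offline, including parameter recovery.
- **A benchmark dataset** — the survivor columns, brood sizes and sex
  counts of a published two-generation trial (six diets × 33 eggs), with a
  deterministic rearing log reconstructed from them.

## Quickstart

```python
from cohortdd import build_life_table, mean_trend, render_life_table
from cohortdd.degree_days import ledgers_for
from cohortdd.reference import reference_dataset

records, temperatures = reference_dataset()
cohort = [r for r in records if r.diet == "D0" and r.generation == 1]
table = build_life_table(cohort, ledgers_for(cohort, temperatures))
print(render_life_table(table))
```

```text
D0
Instar (x)  Number Living (N)  Fraction Surviving (lx)  Period Survival (px)  Period Mortality (qx)  Frequence of Deaths (dx)  Expectation of Life (ADD) (ex)
First generation
EG  33  1.00  1.00  0.00  0.00  3010.9
N1  33  1.00  0.97  0.03  0.03  2880.9
N2  32  0.97  1.00  0.00  0.00  2746.5
N3  32  0.97  0.97  0.03  0.03  2454.0
N4  31  0.94  0.94  0.06  0.06  2150.0
N5  29  0.88  0.93  0.07  0.06  1727.0
AD  27  0.82  0.00  1.00  0.82  1053.0
EG  624
T_1 = 18.91
```

All survival/mortality columns and the trend are exact ratios of the raw
integer counts; rounding (half-up, two decimals) happens only at render
time. The `ex` column depends on the temperature trace, which for the
benchmark reconstruction is a constant 18–25 °C regime — survivor columns
and trends are observed values, `ex` is illustrative.

How often could the insect cycle in a year? A constant 25 °C supplies
3650 ADD per year above the 15 °C threshold:

```python
from cohortdd import generations_per_year
g = generations_per_year(mean_daily_t=25.0, egg_to_adult_add=1513.0)
g.rate, g.ceiling   # (2.412..., 3)
```

## Command line

```bash
demog simulate --seed 7 --out trial/            # synthetic rearing_log.csv + temperature.csv
demog simulate --fixture reference --out bench/ # the deterministic benchmark log
demog build --log trial/rearing_log.csv --temps trial/temperature.csv --diet Dm
demog stats --log trial/rearing_log.csv --temps trial/temperature.csv
demog report --log trial/rearing_log.csv --temps trial/temperature.csv --out report.json
```

`rearing_log.csv` is one row per individual: stage entry dates
(`date_EG … date_AD`), death date/stage/cause, sex, eggs laid and hatched.
`temperature.csv` is one row per day: `date, tmin, tmax`, strictly
consecutive. A long event-format log can be converted with
`cohortdd.io.from_event_log`.

## Examples

- `examples/reference_tables.py` — rebuilds every benchmark life table from
  its survivor column and prints trends and generations-per-year bounds.
- `examples/synthetic_trial.py` — simulates a six-diet, two-generation
  trial and runs the full analysis on it.

## Testing and reproduction

```bash
python -m pytest -q                                  # full suite (~1 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite includes an acceptance layer (`tests/test_acceptance.py`)
that reproduces the benchmark tables cell by cell from the survivor counts
alone, checks the degree-day engine against a day-by-day loop oracle,
verifies the life-table arithmetic against a naive per-individual replay on
random synthetic cohorts, calibrates the statistics battery under null
generators (rejection rate 0.05 ± 99% binomial bounds over 2000 reps), and
recovers the generator's mortality, development and hatch parameters from
seeded cohorts of 500. Five published cells contradict their own survivor
columns; the suite asserts the arithmetically consistent values there and
records the printed ones (see `ERRATA` in `tests/test_acceptance.py` and
`docs/methods.md`).

## Scope

No intrinsic rate of increase, net reproductive rate or Leslie-matrix
projection; no predictive modelling or clustering; no plotting. The
package stops at life tables, trends and the comparison statistics.
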