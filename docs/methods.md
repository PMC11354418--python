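# Methods

This document records the computational model behind `cohortdd`, the
conventions the numbers depend on, and the design decisions a reader needs
in order to trust — or challenge — the output.

## 1. The degree-day clock

Ectotherm development is paced by heat, not calendar time. The package
uses the **simple-average (historical) method** with a lower developmental
threshold `Tbase = 15 °C`:

```
daily_dd = max(0, (Tmax + Tmin) / 2 − Tbase)
```

- Negative values are clipped to zero by default
  (`DegreeDayParams.negative_clip=True`); a signed variant exists for
  sensitivity checks. Under the laboratory regimes modelled here (daily
  minima ≥ 16 °C) clipping never binds, which the test suite asserts.
- Accumulation over an interval uses **half-open attribution**
  `[entry, exit)`: the day an insect molts is credited to the new stage.
  This makes per-stage ledger entries sum exactly to the egg-to-death
  total (conservation), which is tested to 1e-9.
- The **biofix** (accumulation origin) is oviposition: the egg's entry
  date.
- `generations_per_year(T, add)` divides the annual heat supply
  `365 (T − Tbase)` by the egg-to-adult requirement. At 25 °C the year
  supplies 3650 ADD; the benchmark requirements (1513–2332 ADD) give
  1.57–2.41 generations — at most three per year.

An `ADDLedger` per individual carries ADD per stage, the cumulative
egg-to-adult total (only defined for completers), and the total from the
first instar onward. Individuals censored alive (no death date) get no
entry for their final, unfinished stage.

## 2. Cohort life tables

A cohort of `N(EG)` same-day eggs on one diet is followed through stages
`EG, N1 … N5, AD`. With `N(x)` the number entering stage `x`:

| column | definition | adult row |
|--------|------------|-----------|
| `lx`   | `N(x) / N(EG)` | as defined |
| `px`   | `N(x+1) / N(x)` | `0` (no next stage) |
| `qx`   | `1 − px` | `1` |
| `dx`   | `lx − lx(next)` | `lx` |
| `ex`   | mean ADD from stage entry to death, over entrants with a closed record | as defined |

Conventions worth stating:

- All ratios are computed from **raw integers**; rounding (half-up, two
  decimals, via `Decimal` — `11.425 → 11.43`, not banker's `11.42`)
  happens only at render time. Two invariants hold on the raw values:
  `Σ dx = 1` and `px + qx = 1` in every row.
- After extinction (`N(x) = 0` before adulthood) rows use `px = 0`,
  `qx = 1`, `lx = dx = 0`.
- `ex` averages over individuals that entered the stage **and died during
  the observation window**; it is a cohort life expectancy on the
  degree-day clock, not a projection.

The **population trend** of a brood is
`T = eggs in subsequent brood / eggs in previous brood` (here: total eggs
laid by the cohort's females over the 33 eggs that founded it). `T > 1`
means the caged population grows under that diet. The per-diet mean trend
**averages the two-decimal-rounded per-generation trends** — see section 5.

## 3. Statistics battery

All tests operate at α = 0.05.

- **Sex ratio** (diets × {male, female}): Pearson χ² without continuity
  correction, `df = diets − 1`. Post hoc: standardized Pearson residuals
  `(O − E) / sqrt(E (1 − row/N)(1 − col/N))` with two-sided normal
  p-values, Bonferroni-corrected over all cells. Diets with no sexed
  adults are dropped with a warning.
- **Mortality** (diets × {died, survived}): exact conditional test on the
  full r × 2 table — the Freeman–Halton generalization of Fisher's exact
  test — by complete enumeration of the multivariate hypergeometric null
  with probability ordering (tables no more probable than the observed
  one, with a 1e-7 relative tie guard). For tables whose enumeration grid
  exceeds 6·10⁶ cells, a seeded Monte Carlo estimate over 100 000 draws is
  used instead. Pairwise 2 × 2 exact tests with Bonferroni form the post
  hoc; 2 × 2 p-values agree with `scipy.stats.fisher_exact` to 1e-12.
- **Cumulative ADD to adulthood**: Welch's heteroscedastic one-way ANOVA
  (Satterthwaite fractional denominator df) with **Games–Howell** pairwise
  comparisons (`q = t√2` against the studentized range with
  Welch–Satterthwaite df). Both are implemented from closed forms and
  verified against `pingouin` as an oracle in the test suite. A
  zero-variance group makes Welch's statistic diverge: the test rejects
  outright (p = 0) unless all data are constant, which raises
  `DegenerateDataError`.
- **Per-instar ADD**: Kruskal–Wallis rank test (scipy, standard tie
  correction), one test per instar; instars with fewer than two diets with
  data are skipped with a warning, fully tied data yield `H = 0, p = 1`.
- **Fecundity / hatch rate**: two-way fixed-effects ANOVA
  `response ~ C(diet) + C(generation)` with type-II sums of squares
  (robust to the mild imbalance of unequal female counts), via
  statsmodels. Lilliefors normality of residuals and Levene homogeneity
  across diet × generation cells are reported alongside, not used as
  gates.

**Calibration.** Under null generators matching the simulator's families
(binomial sexes/deaths, lognormal ADD totals), all four headline tests
reject at 0.05 within the 99% binomial band over 2000 replicates
(`cohortdd.calibration`); exact conditional tests sit at or slightly below
the nominal level, as expected for discrete tests.

## 4. The synthetic-cohort generator

`simulate_experiment` emulates the trial design: per diet and generation,
a cohort of 33 eggs laid on one day, under a seasonal laboratory climate
(sinusoidal annual cycle around 18/25 °C daily extremes, Gaussian daily
jitter, a 16 °C floor).

Per individual:

1. Each pre-adult stage draws a **lognormal ADD requirement** with mean
   `stage_add_mean[s]` and a common per-stage coefficient of variation
   (`mu = ln(mean) − σ²/2`, so the expectation equals the configured
   mean).
2. **Development is continuous**: requirements accumulate into a running
   heat target from the biofix, and each molt date is the first day the
   cumulative daily series reaches the target (surplus heat on a molt day
   carries into the next stage). This matters: re-basing each stage at
   whole-day molt dates adds ~1% quantization overshoot per stage sum,
   enough to break 2% parameter recovery.
3. **Mortality** is one Bernoulli draw per stage at entry; a death date is
   placed a uniform fraction of the stage requirement into the stage.
4. At emergence, **sex** is Bernoulli (`male_prob`), females draw a
   normal egg count (truncated at 0) and a binomial hatched count.

Randomness is spawned via `np.random.SeedSequence(seed,
spawn_key=(diet_index, generation))`: identical configurations are
bit-reproducible, and one diet's draws never perturb another's.

**Calibration of the defaults.** The six `DietProfile` defaults are set
so that each diet's egg-to-adult ADD total equals its reported cumulative
mean (1923.96 / 2332 / 1931.89 / 2131.81 / 2191.98 for Dm / D0 / D1 / D3 /
D4); the egg stage takes 128 ADD (the constant egg-to-N1 gap across the
benchmark `ex` columns) and the five instars split the remainder
10/13/17/25/35%. The common per-stage CV is chosen so independent
per-stage lognormals reproduce the reported total SD
(`cv = SD_total / sqrt(Σ meanᵢ²)`). Stage mortalities pool the observed
stage deaths of the two benchmark generations; D0 carries the observed
female-skewed sex ratio (17% males); D2 — the diet on which no individual
completed development — gets synthetic 0.6–0.9 mid-development
mortalities whose only observed property is extinction.

**Scope and limits.** The generator is a test harness, not a biological
model: no density dependence, no prey dynamics, no genetic structure, no
between-individual correlation beyond the shared climate. The published
inferential statistics (χ² = 12.04, F₄,₆₂.₂₉ = 5.16, F₁,₁₄₆ = 5.13), the
reported cumulative-ADD means/SDs, fecundity and hatch means, and all `ex`
columns would require the unpublished raw logs and temperature traces;
they enter only as calibration defaults and sanity envelopes, which the
acceptance suite declares explicitly.

## 5. Numerical and editorial decisions

- **Half-up rounding.** The benchmark tables round half away from zero
  (`26/33 = 0.7879 → 0.79`, `11.425 → 11.43`); Python's `round()`
  (banker's) would disagree. `round_half_up` uses
  `Decimal(repr(x)).quantize(..., ROUND_HALF_UP)`.
- **Mean trend averages rounded terms.** The printed per-diet means are
  reproducible only as the mean of the two-decimal-rounded generation
  trends: e.g. `(10.24 + 12.61)/2 = 11.425 → 11.43`, whereas the raw mean
  is 11.4242 → 11.42. All five benchmark means confirm this;
  `mean_trend(..., rounded=False)` gives the raw average.
- **Errata.** Five published cells contradict their own survivor columns:
  the Dm second-generation N1 `dx` (printed 0, consistent 0.03), the D0
  second-generation EG `px/qx/dx` (printed 1/0/0, consistent
  0.97/0.03/0.03 since N drops 33 → 32), and the D4 second-generation EG
  `px` (printed 0, consistent 1). The acceptance suite asserts the
  consistent values for these cells and the printed values everywhere
  else (275 of 280 cells).
- **Parameter-recovery tolerances.** Recovery asserts mortality within
  ±0.03, mean cumulative ADD within 2%, hatch within 1 point, at n = 500
  and a seed fixed before any recovery test was run. Where a ±0.03 bound
  is statistically unattainable at 99% confidence for the configured rate
  and realized entrants (only D2's 0.6–0.9 stages), the exact 99% binomial
  band is enforced instead — a property of the sampling distribution, not
  a tuned tolerance.
- **Build vs buy.** Standard procedures are delegated (scipy:
  Kruskal–Wallis, Levene, χ² contingency; statsmodels: OLS/ANOVA,
  Lilliefors); procedures central to the analysis or absent from the
  stack are authored and oracle-tested (Welch ANOVA, Games–Howell,
  standardized-residual post hoc, exact r × 2 enumeration).
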