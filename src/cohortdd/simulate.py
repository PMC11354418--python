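"""Seeded stochastic generator of rearing logs and lab temperature series.

The generator emulates a two-generation rearing trial of *Zelus renardii*
cohorts (33 newborns per diet per generation) under a seasonally cycling
laboratory climate (daily minima around 18 degC, maxima around 25 degC):

* each individual draws a lognormal degree-day requirement per stage
  (egg through fifth instar, plus an adult longevity budget), which is
  inverted against the temperature series to produce calendar entry dates;
* mortality is a single Bernoulli draw at each stage entry;
* sex is assigned at adult emergence; females draw a truncated-normal egg
  count and a binomial hatched count.

Diet profiles default to the observed rearing outcomes: egg-to-adult
degree-day totals of roughly 1900-2330 with per-diet dispersions, per-stage
mortalities of 0-12% (D2 excepted, which never completes development),
an approximately 1:1 sex ratio (D0 female-skewed in the defaults),
26-29 eggs per female, and hatch rates above 96%.

Everything is driven by explicit seeds through numpy's SeedSequence
spawning, so identical configurations reproduce bit-identical datasets.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .degree_days import daily_series
from .records import DegreeDayParams, IndividualRecord, TemperatureSeries
from .stages import JUVENILE_STAGES, STAGES, Stage


class SimulationHorizonError(RuntimeError):
    """The temperature series ended before every individual finished or died."""


@dataclass(frozen=True)
class TemperatureModel:
    """Seasonal lab climate: sinusoidal annual cycle plus daily jitter.

    ``tmin_base``/``tmax_base`` are the annual-mean daily extremes; the
    seasonal term shifts both by ``seasonal_amplitude * sin(...)`` peaking
    at ``seasonal_phase_day`` (day of year).  ``floor`` keeps the daily
    minimum safely above the developmental threshold, as in the heated /
    air-conditioned laboratory being emulated.
    """

    tmin_base: float = 18.0
    tmax_base: float = 25.0
    seasonal_amplitude: float = 1.0
    seasonal_phase_day: float = 196.0  # warmest in mid-July
    jitter_sd: float = 0.3
    floor: float = 16.0

    @property
    def annual_mean(self) -> float:
        return (self.tmin_base + self.tmax_base) / 2.0


@dataclass(frozen=True)
class DietProfile:
    """Generative parameters of one diet treatment.

    ``stage_add_mean`` maps each pre-adult stage to its mean degree-day
    requirement (the egg stage defaults to 128 degree-days — the constant
    gap between egg and first-instar life expectancy across the reference
    tables); their sum is the diet's egg-to-adult degree-day target.
    ``stage_add_cv`` is the per-stage lognormal coefficient of variation,
    ``adult_add_mean`` the post-emergence longevity budget (degree-days),
    ``stage_mortality`` the probability of dying during each stage.
    """

    label: str
    stage_add_mean: dict[Stage, float]
    stage_add_cv: float
    stage_mortality: dict[Stage, float]
    adult_add_mean: float = 600.0
    male_prob: float = 0.5
    fecundity_mean: float = 26.0
    fecundity_sd: float = 4.8
    hatch_prob: float = 0.965

    def __post_init__(self):
        for s in JUVENILE_STAGES:
            if s not in self.stage_add_mean:
                raise ValueError(f"{self.label}: missing stage_add_mean[{s.code}]")
            if self.stage_add_mean[s] <= 0:
                raise ValueError(f"{self.label}: nonpositive requirement at {s.code}")
        for p in list(self.stage_mortality.values()) + [self.male_prob, self.hatch_prob]:
            if not 0 <= p <= 1:
                raise ValueError(f"{self.label}: probability outside [0, 1]")

    @property
    def egg_to_adult_add(self) -> float:
        return float(sum(self.stage_add_mean[s] for s in JUVENILE_STAGES))


#: fraction of the post-egg requirement spent in each nymphal instar;
#: rises with instar (late instars are the long, dispersed ones).
_NYMPH_WEIGHTS = {
    Stage.N1: 0.10,
    Stage.N2: 0.13,
    Stage.N3: 0.17,
    Stage.N4: 0.25,
    Stage.N5: 0.35,
}

EGG_ADD_MEAN = 128.0


def _split_requirement(total: float, egg: float = EGG_ADD_MEAN) -> dict[Stage, float]:
    rest = total - egg
    if rest <= 0:
        raise ValueError("egg-to-adult total must exceed the egg requirement")
    out = {Stage.EG: egg}
    out.update({s: w * rest for s, w in _NYMPH_WEIGHTS.items()})
    return out


def _cv_for_total_sd(stage_means: dict[Stage, float], total_sd: float) -> float:
    # independent per-stage lognormals: Var(total) = cv^2 * sum(mean_i^2)
    ss = float(sum(m * m for m in stage_means.values()))
    return total_sd / np.sqrt(ss)


def _profile(label, total, total_sd, mortality, adult_add, male_prob, fec, fec_sd, hatch):
    means = _split_requirement(total)
    return DietProfile(
        label=label,
        stage_add_mean=means,
        stage_add_cv=_cv_for_total_sd(means, total_sd),
        stage_mortality=mortality,
        adult_add_mean=adult_add,
        male_prob=male_prob,
        fecundity_mean=fec,
        fecundity_sd=fec_sd,
        hatch_prob=hatch,
    )


def _mortality(eg=0.0, n1=0.0, n2=0.0, n3=0.0, n4=0.0, n5=0.0):
    return {Stage.EG: eg, Stage.N1: n1, Stage.N2: n2, Stage.N3: n3,
            Stage.N4: n4, Stage.N5: n5}


def default_diet_profiles() -> tuple[DietProfile, ...]:
    """The six diet treatments with defaults calibrated to the reference trial.

    Egg-to-adult degree-day totals and dispersions follow the observed
    per-diet cumulative means/SDs; per-stage mortalities pool the observed
    stage deaths of the two reference generations; D0 carries the observed
    female-skewed sex ratio; D2 is the failing diet on which no individual
    completes development.
    """
    return (
        _profile("Dm", 1923.96, 466.98,
                 _mortality(n3=0.030, n4=0.031, n5=0.033),
                 520.0, 0.55, 26.92, 6.52, 0.967),
        _profile("D0", 2332.00, 361.10,
                 _mortality(eg=0.015, n1=0.031, n2=0.031, n3=0.050, n4=0.034),
                 1050.0, 0.17, 25.45, 5.05, 0.975),
        _profile("D1", 1931.89, 255.40,
                 _mortality(n1=0.045, n2=0.016, n3=0.049, n4=0.034, n5=0.018),
                 580.0, 0.50, 26.50, 5.00, 0.962),
        _profile("D2", 2000.00, 300.00,
                 _mortality(eg=0.05, n1=0.60, n2=0.60, n3=0.70, n4=0.80, n5=0.90),
                 600.0, 0.50, 26.00, 5.00, 0.960),
        _profile("D3", 2131.81, 321.27,
                 _mortality(n1=0.076, n2=0.049, n3=0.034, n4=0.019, n5=0.019),
                 770.0, 0.45, 27.50, 5.50, 0.969),
        _profile("D4", 2191.98, 448.72,
                 _mortality(n1=0.045, n2=0.048, n3=0.033, n4=0.018, n5=0.018),
                 535.0, 0.55, 26.50, 5.00, 0.962),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs, seeds included."""

    seed: int = 0
    cohort_size: int = 33
    generations: int = 2
    start_date: dt.date = dt.date(2021, 4, 1)
    n_days: int = 1500
    generation_gap_days: int = 480  # second brood starts this long after the first
    temp_model: TemperatureModel = field(default_factory=TemperatureModel)
    diets: tuple[DietProfile, ...] = field(default_factory=default_diet_profiles)
    dd_params: DegreeDayParams = field(default_factory=DegreeDayParams)

    def diet(self, label: str) -> DietProfile:
        for d in self.diets:
            if d.label == label:
                return d
        raise KeyError(label)


def _rng(config: SimulationConfig, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=spawn_key))


def simulate_temperatures(
    config: SimulationConfig,
    start_date: dt.date | None = None,
    n_days: int | None = None,
) -> TemperatureSeries:
    """Daily (tmin, tmax) series under the configured seasonal lab climate."""
    m = config.temp_model
    start = start_date or config.start_date
    n = n_days or config.n_days
    if n < 1:
        raise ValueError("n_days must be >= 1")
    rng = _rng(config, 99)
    doy = np.array([(start + dt.timedelta(days=int(i))).timetuple().tm_yday
                    for i in range(n)], dtype=float)
    seasonal = m.seasonal_amplitude * np.sin(
        2 * np.pi * (doy - m.seasonal_phase_day) / 365.25 + np.pi / 2
    )
    tmin = m.tmin_base + seasonal + rng.normal(0, m.jitter_sd, n)
    tmax = m.tmax_base + seasonal + rng.normal(0, m.jitter_sd, n)
    tmin = np.maximum(tmin, m.floor)
    tmax = np.maximum(tmax, tmin)
    return TemperatureSeries(start=start, tmin=tmin, tmax=tmax)


def _lognormal(rng, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_cohort(
    config: SimulationConfig,
    diet: DietProfile,
    generation: int,
    series: TemperatureSeries,
    start_date: dt.date | None = None,
    cohort_size: int | None = None,
) -> list[IndividualRecord]:
    """Simulate one cohort of same-day eggs on one diet.

    Degree-day requirements are drawn per stage, then inverted against the
    series' daily degree-day accumulation to yield calendar entry dates:
    the molt is recorded on the day the running total first reaches the
    requirement.  Reproducible: the random stream is spawned from
    (config.seed, diet, generation).
    """
    n = cohort_size or config.cohort_size
    diet_index = [d.label for d in config.diets].index(diet.label)
    rng = _rng(config, diet_index, generation)
    if start_date is None:
        start_date = config.start_date + dt.timedelta(
            days=(generation - 1) * config.generation_gap_days
        )
    dd = daily_series(series, config.dd_params)
    cum = np.concatenate([[0.0], np.cumsum(dd)])

    def day_reaching(target: float, not_before: int) -> int:
        """First day index by which the running heat total reaches `target`.

        Development is continuous: surplus heat on a molt day carries over
        to the next stage, so targets accumulate from the biofix instead of
        re-basing at each (whole-day) molt date.
        """
        j = int(np.searchsorted(cum, target, side="left"))
        if j > len(series):
            raise SimulationHorizonError(
                "temperature series ends before the cohort finishes "
                f"(needed {target - cum[not_before]:.0f} more degree-days)"
            )
        return max(j, not_before)

    records: list[IndividualRecord] = []
    start_idx = series.index_of(start_date)
    if start_idx < 0:
        raise ValueError("cohort starts before the temperature series")
    for i in range(n):
        entry: dict[Stage, dt.date] = {Stage.EG: start_date}
        idx = start_idx
        target = cum[start_idx]
        death_idx: int | None = None
        death_stage: Stage | None = None
        for s in JUVENILE_STAGES:
            req = _lognormal(rng, diet.stage_add_mean[s], diet.stage_add_cv)
            dies = rng.random() < diet.stage_mortality.get(s, 0.0)
            if dies:
                death_idx = day_reaching(target + float(rng.random()) * req, idx)
                death_stage = s
                break
            target += req
            idx = day_reaching(target, idx)
            entry[s.next()] = series.start + dt.timedelta(days=idx)
        sex = eggs = hatched = None
        if death_stage is None:
            # reached adulthood; adults die after an extra heat budget
            sex = "male" if rng.random() < diet.male_prob else "female"
            adult_req = _lognormal(rng, diet.adult_add_mean, diet.stage_add_cv)
            death_idx = day_reaching(target + adult_req, idx)
            death_stage = Stage.AD
            if sex == "female":
                eggs = max(0, int(round(rng.normal(diet.fecundity_mean, diet.fecundity_sd))))
                hatched = int(rng.binomial(eggs, diet.hatch_prob))
        records.append(
            IndividualRecord(
                individual_id=f"{diet.label}-g{generation}-{i:03d}",
                diet=diet.label,
                generation=generation,
                entry_dates=entry,
                death_date=series.start + dt.timedelta(days=death_idx),
                death_stage=death_stage,
                death_cause="did not complete stage" if death_stage is not Stage.AD else "senescence",
                sex=sex,
                eggs_laid=eggs,
                eggs_hatched=hatched,
            )
        )
    return records


@dataclass(frozen=True)
class RearingDataset:
    """A simulated trial: all records plus the temperature series behind them."""

    records: tuple[IndividualRecord, ...]
    series: TemperatureSeries

    def cohort(self, diet: str, generation: int) -> list[IndividualRecord]:
        return [r for r in self.records
                if r.diet == diet and r.generation == generation]

    @property
    def diets(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.diet not in seen:
                seen.append(r.diet)
        return seen


def simulate_experiment(config: SimulationConfig) -> RearingDataset:
    """Simulate the full trial: every diet, every generation, one climate.

    The second generation's eggs are laid by the first generation's females;
    its cohort starts ``generation_gap_days`` after the first, emulating the
    egg-to-egg turnaround.  Diets whose first generation produces no females
    (total developmental failure) get no second cohort, as in the trial
    design being emulated.
    """
    series = simulate_temperatures(config)
    records: list[IndividualRecord] = []
    for diet in config.diets:
        for gen in range(1, config.generations + 1):
            if gen > 1:
                prev = [r for r in records
                        if r.diet == diet.label and r.generation == gen - 1]
                if not any(r.sex == "female" and (r.eggs_hatched or 0) > 0 for r in prev):
                    break
            records.extend(simulate_cohort(config, diet, gen, series))
    return RearingDataset(tuple(records), series)
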