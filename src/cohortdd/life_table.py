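"""Cohort life tables with degree-day life expectancy, and population trend.

A cohort life table follows a fixed group (here 33 same-aged eggs on one
diet) through its stages and tabulates, per stage x:

    N(x)   number alive at entry to the stage
    lx     fraction surviving from cohort start, N(x)/N(EG)
    px     period (stage-to-stage) survival, N(x+1)/N(x); 0 for adults
    qx     period mortality, 1 - px
    dx     fraction of the original cohort dying in the stage, lx - lx(x+1)
    ex     life expectancy at stage entry, in accumulated degree-days

The population trend T divides the egg count of the subsequent brood by the
egg count of the previous one: T > 1 means the caged population grows under
that diet, T = 1 equilibrium, T < 1 decline.

All ratios are computed from raw integer counts; rounding happens only at
render time (see :mod:`cohortdd.io`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import numpy as np

from .degree_days import ADDLedger
from .records import IndividualRecord
from .stages import STAGES, Stage


class EmptyCohortError(ValueError):
    """A life table cannot be built from a cohort with no eggs."""


class UndefinedTrendError(ValueError):
    """The previous brood is empty, so the trend ratio is undefined."""


def stage_counts(records: Sequence[IndividualRecord]) -> np.ndarray:
    """Number living N(x): individuals with an entry date for each stage.

    All records must share one diet and one generation; mixing cohorts
    would silently average survival across treatments.
    """
    if not records:
        return np.zeros(len(STAGES), dtype=int)
    diets = {r.diet for r in records}
    gens = {r.generation for r in records}
    if len(diets) > 1 or len(gens) > 1:
        raise ValueError(f"records mix diets {diets} / generations {gens}")
    return np.array([sum(r.reached(s) for r in records) for s in STAGES], dtype=int)


@dataclass(frozen=True)
class LifeTableRow:
    stage: Stage
    n_living: int
    lx: float
    px: float
    qx: float
    dx: float
    ex: float | None = None


@dataclass(frozen=True)
class LifeTable:
    diet: str
    generation: int
    rows: tuple[LifeTableRow, ...]
    cohort_size: int
    eggs_next_brood: int
    trend: float
    death_tally: Mapping[Stage, Mapping[str, int]] = field(default_factory=dict)

    def row(self, stage: Stage) -> LifeTableRow:
        return self.rows[stage.value]

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.n_living for r in self.rows], dtype=int)


def life_table_from_counts(
    diet: str,
    generation: int,
    counts: Sequence[int],
    eggs_next_brood: int,
    ex: Mapping[Stage, float] | None = None,
    death_tally: Mapping[Stage, Mapping[str, int]] | None = None,
) -> LifeTable:
    """Build a life table from the per-stage N column alone.

    This is the arithmetic core: every lx/px/qx/dx cell is a ratio of the
    raw integers in ``counts``.  ``ex`` (degree-day life expectancy) cannot
    be derived from counts and is attached if supplied.
    """
    counts = np.asarray(counts, dtype=int)
    if len(counts) != len(STAGES):
        raise ValueError(f"expected {len(STAGES)} stage counts, got {len(counts)}")
    if counts[0] <= 0:
        raise EmptyCohortError("cohort has no eggs")
    if np.any(np.diff(counts) > 0):
        raise ValueError("stage counts must be nonincreasing")
    n0 = int(counts[0])
    ex = ex or {}
    rows = []
    for s in STAGES:
        n = int(counts[s.value])
        lx = n / n0
        if s.is_terminal or n == 0:
            px = 0.0
            qx = 1.0
        else:
            px = int(counts[s.value + 1]) / n
            qx = 1.0 - px
        if s.is_terminal:
            dx = lx
        else:
            dx = lx - int(counts[s.value + 1]) / n0
        rows.append(LifeTableRow(s, n, lx, px, qx, dx, ex.get(s)))
    if eggs_next_brood < 0:
        raise ValueError("eggs_next_brood must be nonnegative")
    trend = eggs_next_brood / n0
    return LifeTable(
        diet=diet,
        generation=generation,
        rows=tuple(rows),
        cohort_size=n0,
        eggs_next_brood=int(eggs_next_brood),
        trend=trend,
        death_tally=death_tally or {},
    )


def life_expectancies(
    records: Sequence[IndividualRecord],
    ledgers: Mapping[str, ADDLedger],
) -> dict[Stage, float]:
    """ex per stage: mean degree-days from stage entry to death.

    Averaged over the individuals that entered the stage and have a closed
    ledger (a death date); individuals censored alive are excluded.
    """
    out: dict[Stage, float] = {}
    for s in STAGES:
        vals = [
            ledgers[r.individual_id].add_from(s)
            for r in records
            if r.reached(s)
            and r.individual_id in ledgers
            and r.death_date is not None
        ]
        if vals:
            out[s] = fmean(vals)
    return out


def brood_egg_total(records: Iterable[IndividualRecord]) -> int:
    """Total eggs laid by the cohort's females — the next brood's egg count."""
    return int(sum(r.eggs_laid or 0 for r in records if r.sex == "female"))


def death_tally(records: Iterable[IndividualRecord]) -> dict[Stage, dict[str, int]]:
    """Free-text death-cause counts grouped by the stage of death."""
    tally: dict[Stage, Counter] = {}
    for r in records:
        if r.death_date is None:
            continue
        stage = r.death_stage if r.death_stage is not None else r.last_stage
        cause = r.death_cause or "unspecified"
        tally.setdefault(stage, Counter())[cause] += 1
    return {s: dict(c) for s, c in tally.items()}


def build_life_table(
    records: Sequence[IndividualRecord],
    ledgers: Mapping[str, ADDLedger] | None = None,
    eggs_next_brood: int | None = None,
) -> LifeTable:
    """Life table of one cohort from its rearing records.

    ``eggs_next_brood`` defaults to the total eggs laid by the cohort's own
    females, which is how the subsequent brood originates in a closed
    rearing system.
    """
    if not records:
        raise EmptyCohortError("no records")
    counts = stage_counts(records)
    if eggs_next_brood is None:
        eggs_next_brood = brood_egg_total(records)
    ex = life_expectancies(records, ledgers) if ledgers else None
    return life_table_from_counts(
        diet=records[0].diet,
        generation=records[0].generation,
        counts=counts,
        eggs_next_brood=eggs_next_brood,
        ex=ex,
        death_tally=death_tally(records),
    )


def population_trend(eggs_prev: int, eggs_next: int) -> float:
    """Trend T = eggs in the subsequent brood / eggs in the previous brood."""
    if eggs_prev <= 0:
        raise UndefinedTrendError("previous brood has no eggs")
    if eggs_next < 0:
        raise ValueError("egg counts must be nonnegative")
    return eggs_next / eggs_prev


def classify_trend(t: float) -> str:
    """'growing' (T>1), 'declining' (T<1) or 'equilibrium' (T=1)."""
    if t > 1:
        return "growing"
    if t < 1:
        return "declining"
    return "equilibrium"


@dataclass(frozen=True)
class TrendEstimate:
    """Per-generation trends and their per-treatment average."""

    trends: tuple[float, ...]
    t_mean: float

    @property
    def t1(self) -> float:
        return self.trends[0]

    @property
    def t2(self) -> float:
        return self.trends[1]


def mean_trend(trends: Sequence[float], rounded: bool = True) -> TrendEstimate:
    """Average trend across generations for one treatment.

    With ``rounded`` (the default) each per-generation trend is first
    rounded half-up to 2 decimals, matching how the treatment means in the
    source tables were evidently formed (e.g. (10.24 + 12.61)/2 = 11.425
    -> 11.43, which the unrounded mean 11.4242 cannot yield).
    """
    from .io import round_half_up  # local import to avoid cycle

    if not trends:
        raise ValueError("need at least one trend")
    vals = [round_half_up(t, 2) for t in trends] if rounded else list(trends)
    return TrendEstimate(tuple(float(t) for t in trends), fmean(vals))
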