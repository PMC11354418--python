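"""Accumulated degree-days (ADD): the developmental clock of ectotherms.

Development speed in insects is driven by heat accumulation above a lower
threshold temperature rather than by calendar time.  The simple-average
method scores each day as ``(Tmax + Tmin)/2 - Tbase``, clipped at zero, and
sums those contributions between two events.  Here the biofix (accumulation
start) is oviposition, and every duration in the analysis — stage lengths,
life expectancies — is denominated in degree-days (degC * day).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping

import numpy as np

from .records import DegreeDayParams, IndividualRecord, TemperatureSeries
from .stages import STAGES, JUVENILE_STAGES, Stage


class CoverageError(ValueError):
    """An event interval falls outside the temperature series."""


def daily_dd(tmax: float, tmin: float, params: DegreeDayParams = DegreeDayParams()) -> float:
    """Degree-days contributed by a single day with extremes (tmax, tmin).

    Returns ``(tmax + tmin)/2 - tbase``, floored at 0 when
    ``params.negative_clip`` is set.
    """
    if not (math.isfinite(tmax) and math.isfinite(tmin)):
        raise ValueError("temperatures must be finite")
    if tmin > tmax:
        raise ValueError(f"tmin ({tmin}) exceeds tmax ({tmax})")
    dd = (tmax + tmin) / 2.0 - params.tbase
    if params.negative_clip:
        dd = max(0.0, dd)
    return dd


def daily_series(series: TemperatureSeries, params: DegreeDayParams = DegreeDayParams()) -> np.ndarray:
    """Vector of daily degree-day contributions for a whole series."""
    dd = (series.tmax + series.tmin) / 2.0 - params.tbase
    if params.negative_clip:
        dd = np.maximum(dd, 0.0)
    return dd


def accumulate(
    series: TemperatureSeries,
    start: date,
    end: date,
    params: DegreeDayParams = DegreeDayParams(),
) -> float:
    """Sum daily degree-days over the half-open interval [start, end).

    The day an event occurs belongs to the interval that starts on it, so
    intervals chain without double-counting: accumulate(a, b) +
    accumulate(b, c) == accumulate(a, c).
    """
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    if start == end:
        return 0.0
    if not series.covers(start, end):
        raise CoverageError(
            f"series covers [{series.start}, {series.end}) but "
            f"[{start}, {end}) was requested"
        )
    i, j = series.index_of(start), series.index_of(end)
    return float(np.sum(daily_series(series, params)[i:j]))


@dataclass(frozen=True)
class ADDLedger:
    """Per-stage degree-day account for one individual.

    ``add[stage]`` is the heat accumulated between entry to that stage and
    entry to the next stage (or death for the last stage observed);
    ``n_days[stage]`` the matching day count.  ``cumulative_add`` is the
    biofix-to-adult total (egg through fifth instar) and is only defined
    for individuals that reached the adult stage; ``cumulative_add_from_n1``
    drops the egg stage, since a reported "cumulative ADD" may or may not
    include embryonic development.
    """

    individual_id: str
    add: Mapping[Stage, float]
    n_days: Mapping[Stage, int]

    @property
    def cumulative_add(self) -> float | None:
        if Stage.AD not in self.add:
            return None
        return float(sum(self.add[s] for s in JUVENILE_STAGES))

    @property
    def cumulative_add_from_n1(self) -> float | None:
        if Stage.AD not in self.add:
            return None
        return float(sum(self.add[s] for s in JUVENILE_STAGES if s is not Stage.EG))

    def add_from(self, stage: Stage) -> float:
        """Heat from entry to `stage` through the end of the account (death)."""
        return float(sum(v for s, v in self.add.items() if s >= stage))

    @property
    def total(self) -> float:
        """Biofix-to-death total."""
        return float(sum(self.add.values()))


def ledger_for(
    record: IndividualRecord,
    series: TemperatureSeries,
    params: DegreeDayParams = DegreeDayParams(),
) -> ADDLedger:
    """Build the per-stage degree-day ledger of one individual.

    Each stage's account runs from its entry date to the next stage's entry
    date; the last stage observed runs to the death date.  An individual
    with no death date (censored while alive) gets no account for its last
    stage, since that interval has no endpoint yet.
    """
    add: dict[Stage, float] = {}
    n_days: dict[Stage, int] = {}
    reached = [s for s in STAGES if record.reached(s)]
    for s in reached:
        entry = record.entry_dates[s]
        nxt = s.next()
        if nxt is not None and record.reached(nxt):
            exit_ = record.entry_dates[nxt]
        elif record.death_date is not None:
            exit_ = record.death_date
        else:
            continue  # censored: open-ended last stage
        add[s] = accumulate(series, entry, exit_, params)
        n_days[s] = (exit_ - entry).days
    return ADDLedger(record.individual_id, add, n_days)


def ledgers_for(
    records: Iterable[IndividualRecord],
    series: TemperatureSeries,
    params: DegreeDayParams = DegreeDayParams(),
) -> dict[str, ADDLedger]:
    return {r.individual_id: ledger_for(r, series, params) for r in records}


@dataclass(frozen=True)
class GenerationsPerYear:
    """Annual voltinism estimate: how many life cycles fit in a year's heat."""

    rate: float
    ceiling: int


def generations_per_year(
    mean_daily_t: float,
    egg_to_adult_add: float,
    params: DegreeDayParams = DegreeDayParams(),
) -> GenerationsPerYear:
    """Generations per year at a constant mean temperature.

    A year at mean temperature T supplies 365 * (T - Tbase) degree-days; a
    generation consumes ``egg_to_adult_add`` of them.  At or below the
    developmental threshold no heat accrues and the rate is zero — a
    no-development signal, not an error.
    """
    if egg_to_adult_add <= 0:
        raise ValueError("egg_to_adult_add must be positive")
    annual = 365.0 * (mean_daily_t - params.tbase)
    if annual <= 0:
        return GenerationsPerYear(0.0, 0)
    rate = annual / egg_to_adult_add
    return GenerationsPerYear(rate, math.ceil(rate))
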