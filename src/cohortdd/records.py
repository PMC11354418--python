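"""Core domain types: reared individuals, temperature series, degree-day parameters.

These are deliberately plain containers with explicit ``validate`` methods:
rearing logs are hand-entered, so validation collects every problem it can
find instead of failing on the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping

import numpy as np

from .stages import STAGES, Stage

DIETS = ("Dm", "D0", "D1", "D2", "D3", "D4")

SEXES = ("male", "female")


class ValidationError(ValueError):
    """Raised when one or more rows of an input violate an invariant.

    ``problems`` holds every message collected, one per violation.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class IndividualRecord:
    """One reared insect followed from oviposition to death.

    ``entry_dates`` maps each stage the individual reached to the calendar
    date it entered that stage; the EG entry is the oviposition date and the
    biofix for degree-day accounting.  ``eggs_laid``/``eggs_hatched`` are
    only meaningful for females.
    """

    individual_id: str
    diet: str
    generation: int
    entry_dates: Mapping[Stage, date]
    death_date: date | None = None
    death_stage: Stage | None = None
    death_cause: str | None = None
    sex: str | None = None
    eggs_laid: int | None = None
    eggs_hatched: int | None = None

    def reached(self, stage: Stage) -> bool:
        return stage in self.entry_dates

    @property
    def last_stage(self) -> Stage:
        """The most advanced stage with an entry date."""
        return max(self.entry_dates)

    def problems(self) -> list[str]:
        """Collect every invariant violation for this record."""
        out: list[str] = []
        pid = self.individual_id
        if self.diet not in DIETS:
            out.append(f"{pid}: unknown diet {self.diet!r}")
        if Stage.EG not in self.entry_dates:
            out.append(f"{pid}: missing EG (oviposition) date")
            return out
        # contiguity and monotonicity of stage entries
        prev: Stage | None = None
        for s in STAGES:
            if s in self.entry_dates:
                if prev is not None and prev.next() is not s:
                    out.append(f"{pid}: stage {s.code} entered but {prev.next().code} missing")
                if prev is not None and self.entry_dates[s] < self.entry_dates[prev]:
                    out.append(
                        f"{pid}: {s.code} entry {self.entry_dates[s]} precedes "
                        f"{prev.code} entry {self.entry_dates[prev]}"
                    )
                prev = s
        if self.death_stage is not None and self.death_stage is not self.last_stage:
            out.append(
                f"{pid}: death_stage {self.death_stage.code} is not the last stage "
                f"entered ({self.last_stage.code})"
            )
        if self.death_date is not None and self.death_date < self.entry_dates[self.last_stage]:
            out.append(f"{pid}: death date precedes last stage entry")
        if self.sex in SEXES and not self.reached(Stage.AD):
            out.append(f"{pid}: sex recorded but adult stage never reached")
        if self.sex is not None and self.sex not in SEXES + ("undetermined",):
            out.append(f"{pid}: unknown sex {self.sex!r}")
        if self.eggs_laid is not None:
            if self.sex != "female":
                out.append(f"{pid}: eggs recorded for a non-female")
            if self.eggs_laid < 0:
                out.append(f"{pid}: negative eggs_laid")
        if self.eggs_hatched is not None:
            if self.eggs_laid is None:
                out.append(f"{pid}: eggs_hatched without eggs_laid")
            elif not 0 <= self.eggs_hatched <= self.eggs_laid:
                out.append(f"{pid}: eggs_hatched outside [0, eggs_laid]")
        return out

    def validate(self) -> "IndividualRecord":
        probs = self.problems()
        if probs:
            raise ValidationError(probs)
        return self


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily (Tmin, Tmax) pairs over a gap-free span of calendar dates.

    Stored as a start date plus two aligned arrays, which makes the no-gap
    invariant structural.
    """

    start: date
    tmin: np.ndarray
    tmax: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "tmin", np.asarray(self.tmin, dtype=float))
        object.__setattr__(self, "tmax", np.asarray(self.tmax, dtype=float))
        if self.tmin.shape != self.tmax.shape or self.tmin.ndim != 1:
            raise ValidationError(["tmin and tmax must be 1-d arrays of equal length"])
        if len(self.tmin) == 0:
            raise ValidationError(["temperature series is empty"])
        if not np.all(np.isfinite(self.tmin)) or not np.all(np.isfinite(self.tmax)):
            raise ValidationError(["non-finite temperature value"])
        bad = np.nonzero(self.tmin > self.tmax)[0]
        if bad.size:
            d = self.start + timedelta(days=int(bad[0]))
            raise ValidationError([f"tmin > tmax on {d.isoformat()}"])

    def __len__(self) -> int:
        return len(self.tmin)

    @property
    def end(self) -> date:
        """First date *after* the covered span (exclusive end)."""
        return self.start + timedelta(days=len(self))

    @property
    def dates(self) -> list[date]:
        return [self.start + timedelta(days=i) for i in range(len(self))]

    def index_of(self, d: date) -> int:
        return (d - self.start).days

    def covers(self, start: date, end: date) -> bool:
        """True when the half-open interval [start, end) lies inside the series."""
        return self.start <= start and end <= self.end

    def mean_daily(self) -> float:
        """Long-run mean of the daily average temperature (Tmin+Tmax)/2."""
        return float(np.mean((self.tmin + self.tmax) / 2.0))

    def __eq__(self, other) -> bool:
        if not isinstance(other, TemperatureSeries):
            return NotImplemented
        return (
            self.start == other.start
            and np.array_equal(self.tmin, other.tmin)
            and np.array_equal(self.tmax, other.tmax)
        )


@dataclass(frozen=True)
class DegreeDayParams:
    """Parameters of the simple-average degree-day method.

    ``tbase`` is the lower developmental threshold (15 degC for the
    leafhopper assassin bug); with ``negative_clip`` days colder than the
    threshold contribute zero rather than negative heat.
    """

    tbase: float = 15.0
    negative_clip: bool = True

    def __post_init__(self):
        if not np.isfinite(self.tbase):
            raise ValidationError(["tbase must be finite"])


def validate_records(records: Iterable[IndividualRecord]) -> list[str]:
    """Collect invariant violations across a collection (collect-all, not fail-fast)."""
    out: list[str] = []
    seen: set[str] = set()
    for r in records:
        if r.individual_id in seen:
            out.append(f"{r.individual_id}: duplicate individual_id")
        seen.add(r.individual_id)
        out.extend(r.problems())
    return out
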