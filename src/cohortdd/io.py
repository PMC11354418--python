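"""Reading, writing and rendering: rearing logs, temperature series, life tables.

File formats
------------
``rearing_log.csv`` — one row per individual (wide format), columns::

    individual_id, diet, generation, date_EG, date_N1 ... date_N5, date_AD,
    death_date, death_stage, death_cause, sex, eggs_laid, eggs_hatched

``temperature.csv`` — one row per calendar day, columns ``date, tmin, tmax``,
strictly consecutive dates.

All dates are ISO-8601.  Validation is collect-all: every malformed row is
reported, since rearing logs are hand-entered.
"""

from __future__ import annotations

import datetime as dt
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .life_table import LifeTable
from .records import (
    IndividualRecord,
    TemperatureSeries,
    ValidationError,
    validate_records,
)
from .stages import STAGES, Stage

REARING_COLUMNS = (
    ["individual_id", "diet", "generation"]
    + [f"date_{s.code}" for s in STAGES]
    + ["death_date", "death_stage", "death_cause", "sex", "eggs_laid", "eggs_hatched"]
)

#: columns that must be present in a rearing log (death_cause is optional)
MANDATORY_REARING_COLUMNS = tuple(c for c in REARING_COLUMNS if c != "death_cause")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up, e.g. 29/33 -> 0.88 and 11.425 -> 11.43.

    Ties go away from zero, unlike Python's built-in banker's rounding.
    The float is first re-read through its shortest decimal representation
    so that e.g. 0.875 (stored as 0.87499999...) behaves as printed.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class FormatError(ValueError):
    """The file does not have the expected columns or cell types."""


def _parse_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return dt.date.fromisoformat(str(value).strip())


def _parse_int(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(float(value))


def read_rearing_log(path: str | Path) -> list[IndividualRecord]:
    """Read and validate a rearing log CSV.

    Raises :class:`FormatError` if a mandatory column is missing and
    :class:`~cohortdd.records.ValidationError` listing *every* invalid row
    otherwise.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANDATORY_REARING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"rearing log missing column(s): {', '.join(missing)}")
    records: list[IndividualRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        rid = str(row["individual_id"])
        try:
            entry_dates = {}
            for s in STAGES:
                d = _parse_date(row[f"date_{s.code}"])
                if d is not None:
                    entry_dates[s] = d
            death_stage = None
            if isinstance(row.get("death_stage"), str) and row["death_stage"].strip():
                death_stage = Stage[row["death_stage"].strip()]
            sex = row["sex"] if isinstance(row["sex"], str) and row["sex"].strip() else None
            cause = row.get("death_cause")
            records.append(
                IndividualRecord(
                    individual_id=rid,
                    diet=str(row["diet"]),
                    generation=int(row["generation"]),
                    entry_dates=entry_dates,
                    death_date=_parse_date(row["death_date"]),
                    death_stage=death_stage,
                    death_cause=cause if isinstance(cause, str) and cause.strip() else None,
                    sex=sex,
                    eggs_laid=_parse_int(row["eggs_laid"]),
                    eggs_hatched=_parse_int(row["eggs_hatched"]),
                )
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"row {idx} ({rid}): {exc}")
    problems.extend(validate_records(records))
    if problems:
        raise ValidationError(problems)
    return records


def rearing_log_frame(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "individual_id": r.individual_id,
            "diet": r.diet,
            "generation": r.generation,
        }
        for s in STAGES:
            row[f"date_{s.code}"] = r.entry_dates[s].isoformat() if r.reached(s) else ""
        row["death_date"] = r.death_date.isoformat() if r.death_date else ""
        row["death_stage"] = r.death_stage.code if r.death_stage is not None else ""
        row["death_cause"] = r.death_cause or ""
        row["sex"] = r.sex or ""
        row["eggs_laid"] = "" if r.eggs_laid is None else r.eggs_laid
        row["eggs_hatched"] = "" if r.eggs_hatched is None else r.eggs_hatched
        rows.append(row)
    return pd.DataFrame(rows, columns=REARING_COLUMNS)


def write_rearing_log(records: Iterable[IndividualRecord], path: str | Path) -> None:
    rearing_log_frame(records).to_csv(path, index=False)


def from_event_log(events: pd.DataFrame) -> pd.DataFrame:
    """Convert an event-long log to the wide per-individual format.

    ``events`` needs columns ``individual_id, diet, generation, event,
    date`` and optionally ``value``.  ``event`` is a stage code (entry to
    that stage) or one of ``death``, ``sex``, ``eggs_laid``,
    ``eggs_hatched``, ``death_cause`` (payload in ``value``).
    """
    stage_codes = {s.code for s in STAGES}
    rows: dict[str, dict] = {}
    for _, ev in events.iterrows():
        rid = str(ev["individual_id"])
        row = rows.setdefault(
            rid,
            {c: "" for c in REARING_COLUMNS}
            | {
                "individual_id": rid,
                "diet": ev["diet"],
                "generation": ev["generation"],
            },
        )
        kind = str(ev["event"])
        if kind in stage_codes:
            row[f"date_{kind}"] = str(ev["date"])
        elif kind == "death":
            row["death_date"] = str(ev["date"])
        elif kind in ("sex", "eggs_laid", "eggs_hatched", "death_cause"):
            row[kind] = ev["value"]
        else:
            raise FormatError(f"unknown event kind {kind!r}")
    # fill death_stage from the last stage entered
    for row in rows.values():
        if row["death_date"]:
            entered = [s for s in STAGES if row[f"date_{s.code}"]]
            if entered:
                row["death_stage"] = entered[-1].code
    return pd.DataFrame(list(rows.values()), columns=REARING_COLUMNS)


def read_temperature(path: str | Path) -> TemperatureSeries:
    """Read a daily (date, tmin, tmax) CSV into a gap-free series."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("date", "tmin", "tmax") if c not in df.columns]
    if missing:
        raise FormatError(f"temperature file missing column(s): {', '.join(missing)}")
    try:
        tmin = df["tmin"].astype(float).to_numpy()
        tmax = df["tmax"].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric temperature: {exc}") from exc
    dates = [dt.date.fromisoformat(d.strip()) for d in df["date"]]
    problems = []
    for prev, cur in zip(dates, dates[1:]):
        expected = prev + dt.timedelta(days=1)
        if cur != expected:
            problems.append(f"gap in temperature series: missing {expected.isoformat()}")
    if problems:
        raise ValidationError(problems)
    return TemperatureSeries(start=dates[0], tmin=tmin, tmax=tmax)


def write_temperature(series: TemperatureSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "date": [d.isoformat() for d in series.dates],
            "tmin": series.tmin,
            "tmax": series.tmax,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rendering

_HEADER = (
    "Instar (x)\tNumber Living (N)\tFraction Surviving (lx)\t"
    "Period Survival (px)\tPeriod Mortality (qx)\t"
    "Frequence of Deaths (dx)\tExpectation of Life (ADD) (ex)"
)

_GEN_LABEL = {1: "First generation", 2: "Second generation"}


def _f2(x: float) -> str:
    return f"{round_half_up(x, 2):.2f}"


def render_life_table(table: LifeTable, header: bool = True) -> str:
    """Render one cohort's life table as tab-separated text.

    Ratio columns (lx, px, qx, dx) are printed rounded half-up to 2
    decimals, life expectancy (ex, in degree-days) to 1 decimal, the trend
    T to 2 decimals; rows run egg to adult, then the next brood's egg
    count, then T.  Rendering is a total, deterministic function of the
    table: the same table always produces byte-identical text.
    """
    lines: list[str] = []
    if header:
        lines.append(table.diet)
        lines.append(_HEADER)
    lines.append(_GEN_LABEL.get(table.generation, f"Generation {table.generation}"))
    for row in table.rows:
        ex = "" if row.ex is None else f"{round_half_up(row.ex, 1):.1f}"
        lines.append(
            f"{row.stage.code}\t{row.n_living}\t{_f2(row.lx)}\t{_f2(row.px)}\t"
            f"{_f2(row.qx)}\t{_f2(row.dx)}\t{ex}"
        )
    lines.append(f"EG\t{table.eggs_next_brood}")
    lines.append(f"T_{table.generation} = {_f2(table.trend)}")
    return "\n".join(lines) + "\n"


def render_treatment(tables: Sequence[LifeTable], t_mean: float | None = None) -> str:
    """Render all generations of one diet, ending with the treatment mean trend."""
    diets = {t.diet for t in tables}
    if len(diets) != 1:
        raise ValueError(f"tables mix diets: {diets}")
    parts = [render_life_table(t, header=(i == 0)) for i, t in enumerate(tables)]
    text = "".join(parts)
    if t_mean is not None:
        text += f"T_{tables[0].diet} = {_f2(t_mean)}\n"
    return text


def life_table_frame(tables: Iterable[LifeTable]) -> pd.DataFrame:
    """Tidy per-stage CSV layout: diet, generation, stage, N, lx, px, qx, dx, ex."""
    rows = []
    for t in tables:
        for r in t.rows:
            rows.append(
                {
                    "diet": t.diet,
                    "generation": t.generation,
                    "stage": r.stage.code,
                    "N": r.n_living,
                    "lx": r.lx,
                    "px": r.px,
                    "qx": r.qx,
                    "dx": r.dx,
                    "ex": r.ex,
                }
            )
    return pd.DataFrame(rows)


def ledger_frame(ledgers: Iterable) -> pd.DataFrame:
    """Per-individual, per-stage degree-day ledger as a tidy frame."""
    rows = []
    for led in ledgers:
        for s, add in sorted(led.add.items()):
            rows.append(
                {
                    "individual_id": led.individual_id,
                    "stage": s.code,
                    "n_days": led.n_days[s],
                    "add": add,
                    "cumulative_add": led.cumulative_add,
                }
            )
    return pd.DataFrame(rows)
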