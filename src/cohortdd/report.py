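"""End-to-end pipeline: records + temperatures -> tables, trends, statistics.

This is the orchestration layer a rearing lab would actually run: build the
degree-day ledgers, the per-cohort life tables and trends, then the whole
comparison battery, and emit everything as one JSON-serializable report.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .degree_days import ADDLedger, generations_per_year, ledgers_for
from .life_table import (
    LifeTable,
    brood_egg_total,
    build_life_table,
    classify_trend,
    mean_trend,
)
from .records import DegreeDayParams, IndividualRecord, TemperatureSeries
from .stages import STAGES, Stage
from .stats import (
    DegenerateDataError,
    TestResult,
    fecundity_anova,
    games_howell,
    kruskal_wallis_per_instar,
    mortality_test,
    sex_ratio_test,
    welch_anova,
)


def group_cohorts(
    records: Sequence[IndividualRecord],
) -> dict[str, dict[int, list[IndividualRecord]]]:
    out: dict[str, dict[int, list[IndividualRecord]]] = {}
    for r in records:
        out.setdefault(r.diet, {}).setdefault(r.generation, []).append(r)
    return out


def cohort_life_tables(
    records: Sequence[IndividualRecord],
    series: TemperatureSeries,
    params: DegreeDayParams = DegreeDayParams(),
) -> dict[str, dict[int, LifeTable]]:
    ledgers = ledgers_for(records, series, params)
    return {
        diet: {gen: build_life_table(cohort, ledgers) for gen, cohort in by_gen.items()}
        for diet, by_gen in group_cohorts(records).items()
    }


def stage_add_frame(
    records: Sequence[IndividualRecord],
    ledgers: Mapping[str, ADDLedger],
) -> pd.DataFrame:
    """Tidy per-individual, per-stage degree-day frame for the rank tests."""
    rows = []
    for r in records:
        led = ledgers.get(r.individual_id)
        if led is None:
            continue
        for s, add in led.add.items():
            rows.append(
                {
                    "individual_id": r.individual_id,
                    "diet": r.diet,
                    "generation": r.generation,
                    "stage": s,
                    "add": add,
                }
            )
    return pd.DataFrame(rows)


def sex_table(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    """Diet x (male, female) adult counts; undetermined individuals excluded."""
    diets = sorted({r.diet for r in records})
    data = {
        d: [
            sum(1 for r in records if r.diet == d and r.sex == "male"),
            sum(1 for r in records if r.diet == d and r.sex == "female"),
        ]
        for d in diets
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=["male", "female"])


def mortality_table(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    """Diet x (died, survived): death = failure to reach adulthood."""
    diets = sorted({r.diet for r in records})
    data = {}
    for d in diets:
        cohort = [r for r in records if r.diet == d]
        survived = sum(1 for r in cohort if r.reached(Stage.AD))
        data[d] = [len(cohort) - survived, survived]
    return pd.DataFrame.from_dict(data, orient="index", columns=["died", "survived"])


def fecundity_frame(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.sex == "female" and r.eggs_laid is not None:
            rows.append(
                {
                    "diet": r.diet,
                    "generation": r.generation,
                    "eggs_laid": r.eggs_laid,
                    "hatch_rate": (r.eggs_hatched / r.eggs_laid)
                    if r.eggs_laid and r.eggs_hatched is not None
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, TestResult):
        d = dataclasses.asdict(obj)
        d["extras"] = dict(obj.extras)
        return _jsonable(d)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {_key(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Stage):
        return obj.code
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if hasattr(obj, "isoformat"):
        return obj.isoformat()
    return obj


def _key(k):
    if isinstance(k, Stage):
        return k.code
    return str(k)


def run_report(
    records: Sequence[IndividualRecord],
    series: TemperatureSeries,
    params: DegreeDayParams = DegreeDayParams(),
) -> dict:
    """Compute the full analysis report as a JSON-serializable dict.

    Sections: per-cohort life tables; per-diet trends (per generation and
    treatment mean); sex-ratio, mortality, heteroscedastic ANOVA +
    Games–Howell, and per-instar rank tests, each per generation;
    two-way fecundity and hatch-rate ANOVA; and a generations-per-year
    projection from each diet's mean egg-to-adult degree-day total at the
    series' mean temperature.
    """
    ledgers = ledgers_for(records, series, params)
    cohorts = group_cohorts(records)
    tables = cohort_life_tables(records, series, params)
    generations = sorted({r.generation for r in records})

    trends = {}
    for diet, by_gen in tables.items():
        per_gen = {gen: t.trend for gen, t in sorted(by_gen.items())}
        est = mean_trend(list(per_gen.values()))
        trends[diet] = {
            "per_generation": per_gen,
            "mean": est.t_mean,
            "classification": {g: classify_trend(t) for g, t in per_gen.items()},
        }

    stats_by_gen: dict[int, dict] = {}
    for gen in generations:
        gen_records = [r for r in records if r.generation == gen]
        sec: dict = {}
        stab = sex_table(gen_records)
        if (stab.to_numpy().sum(axis=1) > 0).sum() >= 2:
            sec["sex_ratio"] = sex_ratio_test(stab)
        mtab = mortality_table(gen_records)
        if len(mtab) >= 2:
            sec["mortality"] = mortality_test(mtab)
        cum = {
            diet: [
                led.cumulative_add
                for r in by_gen.get(gen, [])
                if (led := ledgers[r.individual_id]).cumulative_add is not None
            ]
            for diet, by_gen in cohorts.items()
        }
        groups = {d: v for d, v in cum.items() if len(v) >= 2}
        if len(groups) >= 2:
            try:
                sec["welch_cumulative_add"] = welch_anova(list(groups.values()))
                sec["games_howell"] = games_howell(
                    list(groups.values()), list(groups.keys())
                )
            except DegenerateDataError:
                pass
        frame = stage_add_frame(gen_records, ledgers)
        if len(frame):
            sec["kruskal_per_instar"] = kruskal_wallis_per_instar(
                frame[frame["stage"] != Stage.EG]
            )
        stats_by_gen[gen] = sec

    fec = fecundity_frame(records)
    fecundity = {}
    if len(fec) and fec["diet"].nunique() >= 2 and fec["generation"].nunique() >= 2:
        fecundity["eggs_laid"] = fecundity_anova(fec, "eggs_laid")
        fecundity["hatch_rate"] = fecundity_anova(fec.dropna(subset=["hatch_rate"]), "hatch_rate")

    mean_t = series.mean_daily()
    voltinism = {}
    for diet, by_gen in cohorts.items():
        adds = [
            ledgers[r.individual_id].cumulative_add
            for cohort in by_gen.values()
            for r in cohort
            if ledgers[r.individual_id].cumulative_add is not None
        ]
        if adds:
            g = generations_per_year(mean_t, float(np.mean(adds)), params)
            voltinism[diet] = {
                "mean_egg_to_adult_add": float(np.mean(adds)),
                "generations_per_year": g.rate,
                "ceiling": g.ceiling,
            }

    return _jsonable(
        {
            "life_tables": tables,
            "trends": trends,
            "statistics_by_generation": stats_by_gen,
            "fecundity": fecundity,
            "mean_daily_temperature": mean_t,
            "generations_per_year": voltinism,
        }
    )
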