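"""Life-table arithmetic, degree-day life expectancy, population trend."""

import numpy as np
import pytest

from cohortdd import (
    EmptyCohortError,
    UndefinedTrendError,
    build_life_table,
    classify_trend,
    life_table_from_counts,
    mean_trend,
    population_trend,
    stage_counts,
)
from cohortdd.degree_days import ledgers_for
from cohortdd.life_table import brood_egg_total, death_tally, life_expectancies
from cohortdd.reference import REFERENCE_COUNTS, REFERENCE_EGGS, reference_life_tables
from cohortdd.simulate import SimulationConfig, simulate_cohort, simulate_temperatures
from cohortdd.stages import STAGES, Stage


def test_stage_counts_on_reference(reference):
    records, _ = reference
    dm1 = [r for r in records if r.diet == "Dm" and r.generation == 1]
    np.testing.assert_array_equal(stage_counts(dm1), REFERENCE_COUNTS["Dm"][1])


def test_stage_counts_rejects_mixed_cohorts(reference):
    records, _ = reference
    mixed = [r for r in records if r.diet in ("Dm", "D0") and r.generation == 1]
    with pytest.raises(ValueError, match="mix"):
        stage_counts(mixed)


def test_first_brood_oligidic_cells():
    """Hand-checked cells for the oligidic diet's first brood (n=33, 624 eggs)."""
    t = life_table_from_counts("D0", 1, REFERENCE_COUNTS["D0"][1], REFERENCE_EGGS["D0"][1])
    eg = t.row(Stage.EG)
    assert (eg.lx, eg.px) == (1.0, 1.0)
    assert eg.qx == pytest.approx(0.0)
    n5 = t.row(Stage.N5)
    assert n5.n_living == 29
    assert n5.lx == pytest.approx(29 / 33)
    assert n5.px == pytest.approx(27 / 29)
    assert n5.qx == pytest.approx(2 / 29)
    assert n5.dx == pytest.approx(2 / 33)
    ad = t.row(Stage.AD)
    assert (ad.px, ad.qx) == (0.0, 1.0)
    assert ad.dx == pytest.approx(ad.lx)
    assert t.trend == pytest.approx(624 / 33)


def test_extinct_cohort_rows():
    """After extinction (N=0) the convention is px=0, qx=1, lx=dx=0."""
    t = life_table_from_counts("D2", 1, REFERENCE_COUNTS["D2"][1], 0)
    ad = t.row(Stage.AD)
    assert (ad.n_living, ad.lx, ad.px, ad.qx, ad.dx) == (0, 0.0, 0.0, 1.0, 0.0)
    n5 = t.row(Stage.N5)
    assert n5.px == 0.0 and n5.qx == 1.0
    assert n5.dx == pytest.approx(3 / 33)
    assert t.trend == 0.0


def test_counts_validation():
    with pytest.raises(EmptyCohortError):
        life_table_from_counts("Dm", 1, [0] * 7, 0)
    with pytest.raises(ValueError, match="nonincreasing"):
        life_table_from_counts("Dm", 1, [33, 34, 30, 30, 30, 30, 30], 0)
    with pytest.raises(ValueError, match="stage counts"):
        life_table_from_counts("Dm", 1, [33, 30], 0)


@pytest.mark.parametrize("diet", list(REFERENCE_COUNTS))
@pytest.mark.parametrize("gen", [1, 2])
def test_conservation_identities(diet, gen):
    """Sum(dx) = 1 and px + qx = 1 on every reference cohort."""
    if gen not in REFERENCE_COUNTS[diet]:
        pytest.skip("single-brood diet")
    t = life_table_from_counts(diet, gen, REFERENCE_COUNTS[diet][gen], 0)
    assert sum(r.dx for r in t.rows) == pytest.approx(1.0, abs=1e-12)
    for r in t.rows:
        assert r.px + r.qx == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= r.lx <= 1.0 and 0.0 <= r.dx <= 1.0


def test_random_counts_match_naive_replay():
    """Vectorized table vs a per-cell naive replay on random N columns."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n0 = int(rng.integers(1, 60))
        deaths = rng.multinomial(int(rng.integers(0, n0 + 1)), np.full(7, 1 / 7))
        counts = n0 - np.concatenate([[0], np.cumsum(deaths[:-1])])
        counts = np.maximum(counts, 0)
        counts = np.minimum.accumulate(counts)
        t = life_table_from_counts("Dm", 1, counts, 0)
        for s in STAGES:
            row = t.row(s)
            assert row.lx == pytest.approx(counts[s.value] / counts[0])
            if s is Stage.AD:
                assert (row.px, row.qx) == (0.0, 1.0)
                assert row.dx == pytest.approx(row.lx)
            elif counts[s.value] == 0:
                assert (row.px, row.qx) == (0.0, 1.0)
            else:
                assert row.px == pytest.approx(counts[s.value + 1] / counts[s.value])
                assert row.qx == pytest.approx(1 - row.px)
                assert row.dx == pytest.approx(
                    (counts[s.value] - counts[s.value + 1]) / counts[0]
                )


def test_build_from_records_matches_counts(reference):
    records, series = reference
    d3g2 = [r for r in records if r.diet == "D3" and r.generation == 2]
    ledgers = ledgers_for(d3g2, series)
    t = build_life_table(d3g2, ledgers)
    ref = reference_life_tables()["D3"][2]
    np.testing.assert_array_equal(t.counts, ref.counts)
    for s in STAGES:
        assert t.row(s).lx == pytest.approx(ref.row(s).lx)
        assert t.row(s).qx == pytest.approx(ref.row(s).qx)
    assert t.eggs_next_brood == REFERENCE_EGGS["D3"][2]
    # ex is attached and strictly decreasing cohort-wide quantities stay finite
    assert all(t.row(s).ex is None or t.row(s).ex >= 0 for s in STAGES)
    assert t.row(Stage.EG).ex is not None and t.row(Stage.EG).ex > t.row(Stage.AD).ex


def test_life_expectancy_hand_case(constant_25, params):
    """Two eggs: one dies in EG after 3 days, one reaches N1 and dies 5 days in."""
    import datetime as dt

    from cohortdd import IndividualRecord

    start = constant_25.start
    a = IndividualRecord("a", "Dm", 1, {Stage.EG: start},
                         death_date=start + dt.timedelta(days=3), death_stage=Stage.EG)
    b = IndividualRecord(
        "b", "Dm", 1,
        {Stage.EG: start, Stage.N1: start + dt.timedelta(days=4)},
        death_date=start + dt.timedelta(days=9), death_stage=Stage.N1,
    )
    recs = [a, b]
    ledgers = ledgers_for(recs, constant_25, params)
    ex = life_expectancies(recs, ledgers)
    # at 10 dd/day: a accrues 30 from EG; b accrues 90 from EG, 50 from N1
    assert ex[Stage.EG] == pytest.approx((30 + 90) / 2)
    assert ex[Stage.N1] == pytest.approx(50.0)


def test_brood_total_and_death_tally(reference):
    records, _ = reference
    d0g1 = [r for r in records if r.diet == "D0" and r.generation == 1]
    assert brood_egg_total(d0g1) == REFERENCE_EGGS["D0"][1]
    tally = death_tally(d0g1)
    assert sum(sum(c.values()) for c in tally.values()) == 33
    assert tally[Stage.AD] == {"senescence": 27}
    # six pre-adult deaths spread over the stages where counts drop
    assert sum(sum(c.values()) for s, c in tally.items() if s is not Stage.AD) == 6


def test_build_on_simulated_cohort(small_config):
    series = simulate_temperatures(small_config)
    records = simulate_cohort(small_config, small_config.diet("Dm"), 1, series)
    t = build_life_table(records, ledgers_for(records, series))
    assert t.cohort_size == small_config.cohort_size
    assert sum(r.dx for r in t.rows) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# population trend


def test_trend_examples():
    assert population_trend(33, 624) == pytest.approx(624 / 33)
    assert classify_trend(population_trend(33, 624)) == "growing"
    assert classify_trend(population_trend(100, 50)) == "declining"
    assert classify_trend(1.0) == "equilibrium"
    with pytest.raises(UndefinedTrendError):
        population_trend(0, 10)
    with pytest.raises(ValueError):
        population_trend(10, -1)


def test_mean_trend_rounds_each_generation_first():
    """(10.24... + 12.61...)/2 on rounded terms gives 11.425 -> reported 11.43."""
    t1 = population_trend(33, 338)   # 10.2424...
    t2 = population_trend(33, 416)   # 12.6060...
    est = mean_trend([t1, t2])
    assert est.t_mean == pytest.approx(11.425)
    assert est.t1 == pytest.approx(t1) and est.t2 == pytest.approx(t2)
    raw = mean_trend([t1, t2], rounded=False)
    assert raw.t_mean == pytest.approx((t1 + t2) / 2)
    assert raw.t_mean != pytest.approx(11.425, abs=1e-4)


def test_mean_trend_requires_input():
    with pytest.raises(ValueError):
        mean_trend([])
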