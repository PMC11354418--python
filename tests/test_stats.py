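"""Statistics battery: chi-square + residual post hoc, exact r x 2 tests,
Welch ANOVA / Games-Howell, Kruskal-Wallis per instar, fecundity two-way ANOVA.

Authored procedures (Welch, Games-Howell, residual post hoc, exact test) are
checked against independent oracles: scipy's Fisher test, pingouin, and
desk-scale enumeration.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cohortdd.stats import (
    ALPHA,
    DegenerateDataError,
    _rx2_exact_pvalue,
    fecundity_anova,
    games_howell,
    kruskal_wallis_per_instar,
    mortality_test,
    sex_ratio_test,
    welch_anova,
)
from cohortdd.stages import Stage

pingouin = pytest.importorskip("pingouin")


# ---------------------------------------------------------------------------
# sex ratio


def test_sex_ratio_balanced_table_is_null():
    res = sex_ratio_test([[14, 14], [15, 15], [13, 13]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert not any(ph.significant for ph in res.posthoc)


def test_sex_ratio_matches_hand_computed_chi2():
    obs = np.array([[16, 13], [5, 22]], dtype=float)
    res = sex_ratio_test(obs)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    assert res.statistic == pytest.approx(chi2)
    assert res.df == 1.0
    assert res.p_value == pytest.approx(float(sps.chi2.sf(chi2, 1)))


def test_sex_ratio_skewed_diet_flagged_by_residuals():
    tab = pd.DataFrame(
        {"male": [16, 5, 14, 12, 15], "female": [13, 22, 14, 15, 12]},
        index=["Dm", "D0", "D1", "D3", "D4"],
    )
    res = sex_ratio_test(tab)
    flagged = {ph.label for ph in res.posthoc if ph.significant}
    assert flagged and all(lbl.startswith("D0:") for lbl in flagged)
    # residuals in one row are equal and opposite across the two sexes
    by_label = {ph.label: ph.estimate for ph in res.posthoc}
    assert by_label["D0:male"] == pytest.approx(-by_label["D0:female"])


def test_sex_ratio_drops_unsexed_diet_with_warning():
    tab = pd.DataFrame({"male": [16, 0, 14], "female": [13, 0, 14]},
                       index=["Dm", "D2", "D1"])
    with pytest.warns(UserWarning, match="D2"):
        res = sex_ratio_test(tab)
    assert res.df == 1.0  # two diets remain


def test_sex_ratio_rejects_bad_tables():
    with pytest.raises(ValueError):
        sex_ratio_test([[1, 2, 3]])
    with pytest.raises(ValueError):
        sex_ratio_test([[-1, 2], [3, 4]])
    with pytest.raises(ValueError):
        sex_ratio_test([[5, 6]])


# ---------------------------------------------------------------------------
# exact mortality test


@pytest.mark.parametrize(
    "table",
    [
        [[3, 30], [10, 23]],
        [[0, 33], [6, 27]],
        [[33, 0], [1, 32]],
        [[4, 29], [4, 29]],
        [[2, 8], [7, 3]],
    ],
)
def test_two_by_two_matches_scipy_fisher(table):
    obs = np.asarray(table)
    ours = _rx2_exact_pvalue(obs[:, 0], obs.sum(axis=1))
    _, ref = sps.fisher_exact(obs, alternative="two-sided")
    assert ours == pytest.approx(ref, abs=1e-12)


def test_rx2_exact_tiny_enumeration_oracle():
    """3 x 2 table small enough to enumerate by hand-rolled loops."""
    died = np.array([2, 0, 3])
    n = np.array([4, 3, 5])
    d_total = died.sum()

    def logp(d):
        from math import comb, log
        return sum(log(comb(int(ni), int(di))) for ni, di in zip(n, d)) - np.log(
            __import__("math").comb(int(n.sum()), int(d_total))
        )

    obs_lp = logp(died)
    total = 0.0
    for a in range(min(4, d_total) + 1):
        for b in range(min(3, d_total - a) + 1):
            c = d_total - a - b
            if 0 <= c <= 5:
                lp = logp((a, b, c))
                if lp <= obs_lp + 1e-7:
                    total += np.exp(lp)
    assert _rx2_exact_pvalue(died, n) == pytest.approx(total, rel=1e-10)


def test_mortality_identical_diets_p_one():
    res = mortality_test([[4, 29], [4, 29], [4, 29]])
    assert res.p_value == pytest.approx(1.0)
    assert all(not ph.significant for ph in res.posthoc)
    assert all(ph.estimate == pytest.approx(0.0) for ph in res.posthoc)


def test_mortality_full_mortality_diet_detected():
    # one diet loses the whole cohort while others lose a handful
    tab = pd.DataFrame(
        {"died": [4, 33, 5], "survived": [29, 0, 28]}, index=["Dm", "D2", "D1"]
    )
    res = mortality_test(tab)
    assert res.p_value < 1e-9
    sig = {ph.label for ph in res.posthoc if ph.significant}
    assert sig == {"Dm-D2", "D2-D1"}
    by = {ph.label: ph.estimate for ph in res.posthoc}
    assert by["Dm-D2"] == pytest.approx(4 / 33 - 1.0)


def test_mortality_bonferroni_never_below_raw():
    res = mortality_test([[3, 30], [10, 23], [6, 27], [1, 32]])
    for ph in res.posthoc:
        assert ph.p_adjusted >= ph.p_raw - 1e-15
        assert ph.p_adjusted <= 1.0


def test_mortality_monte_carlo_branch_agrees_with_enumeration():
    """Force the MC fallback on a table the enumerator can also handle."""
    import cohortdd.stats as cs

    tab = [[5, 28], [12, 21], [8, 25], [2, 31]]
    obs = np.asarray(tab)
    exact = _rx2_exact_pvalue(obs[:, 0], obs.sum(axis=1))
    old = cs._ENUM_LIMIT
    cs._spectrum_cache.clear()
    cs._ENUM_LIMIT = 1
    try:
        mc = _rx2_exact_pvalue(obs[:, 0], obs.sum(axis=1),
                               rng=np.random.default_rng(99))
    finally:
        cs._ENUM_LIMIT = old
        cs._spectrum_cache.clear()
    assert mc == pytest.approx(exact, abs=0.01)


# ---------------------------------------------------------------------------
# Welch ANOVA / Games-Howell


@pytest.fixture(scope="module")
def add_groups():
    rng = np.random.default_rng(7)
    return [
        rng.normal(1900, 420, 29),
        rng.normal(2330, 360, 27),
        rng.normal(1930, 250, 28),
        rng.normal(2130, 320, 27),
    ]


def test_welch_matches_pingouin(add_groups):
    res = welch_anova(add_groups)
    df = pd.DataFrame(
        {
            "add": np.concatenate(add_groups),
            "diet": np.repeat([f"g{i}" for i in range(4)],
                              [len(g) for g in add_groups]),
        }
    )
    ref = pingouin.welch_anova(data=df, dv="add", between="diet")
    assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
    assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)
    assert res.df[0] == pytest.approx(float(ref["ddof1"][0]))
    assert res.df[1] == pytest.approx(float(ref["ddof2"][0]), rel=1e-9)


def test_welch_reduces_to_classical_f_for_equal_variances():
    """With equal n and identical sample variances, Welch's F equals the
    classical one-way F up to the small-sample correction factor b."""
    base = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    groups = [base + 0.0, base + 1.0, base + 2.5]
    res = welch_anova(groups)
    f_classic, _ = sps.f_oneway(*groups)
    k, n = 3, 5
    lam = sum((1 - 1 / k) ** 2 / (n - 1) for _ in range(k))
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    assert res.statistic == pytest.approx(f_classic / b, rel=1e-12)


def test_welch_zero_variance_group_rejects():
    res = welch_anova([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
    assert np.isinf(res.statistic) and res.p_value == 0.0


def test_welch_degenerate_constant_data():
    with pytest.raises(DegenerateDataError):
        welch_anova([[2.0, 2.0], [2.0, 2.0]])
    with pytest.raises(ValueError):
        welch_anova([[1.0, 2.0]])
    with pytest.raises(ValueError):
        welch_anova([[1.0], [2.0, 3.0]])


def test_games_howell_matches_pingouin(add_groups):
    labels = ["Dm", "D0", "D1", "D3"]
    ours = games_howell(add_groups, labels)
    df = pd.DataFrame(
        {
            "add": np.concatenate(add_groups),
            "diet": np.repeat(labels, [len(g) for g in add_groups]),
        }
    )
    ref = pingouin.pairwise_gameshowell(data=df, dv="add", between="diet")
    ref_by_pair = {
        frozenset((row["A"], row["B"])): row for _, row in ref.iterrows()
    }
    assert len(ours) == 6
    for r in ours:
        a, b = r.posthoc[0].label.split("-")
        row = ref_by_pair[frozenset((a, b))]
        assert abs(r.statistic) == pytest.approx(abs(float(row["T"])), rel=1e-9)
        assert r.df == pytest.approx(float(row["df"]), rel=1e-9)
        assert r.p_value == pytest.approx(float(row["pval"]), rel=1e-6, abs=1e-9)


def test_games_howell_identical_groups():
    g = [1.0, 2.0, 3.0]
    res = games_howell([g, g])
    assert res[0].p_value == pytest.approx(1.0)
    assert res[0].statistic == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Kruskal-Wallis per instar


def _instar_frame(rng, shift=0.0, n=25):
    rows = []
    for stage in (Stage.N1, Stage.N2):
        for diet, mu in (("Dm", 300.0), ("D1", 300.0 + shift)):
            for v in rng.normal(mu, 30, n):
                rows.append({"stage": stage, "diet": diet, "add": v})
    return pd.DataFrame(rows)


def test_kruskal_matches_scipy():
    rng = np.random.default_rng(3)
    frame = _instar_frame(rng, shift=40.0)
    res = kruskal_wallis_per_instar(frame)
    for stage in (Stage.N1, Stage.N2):
        sub = frame[frame["stage"] == stage]
        groups = [g["add"].to_numpy() for _, g in sub.groupby("diet")]
        h, p = sps.kruskal(*groups)
        assert res[stage].statistic == pytest.approx(h)
        assert res[stage].p_value == pytest.approx(p)


def test_kruskal_null_vs_shift_power():
    rng = np.random.default_rng(11)
    null = kruskal_wallis_per_instar(_instar_frame(rng, shift=0.0))
    shifted = kruskal_wallis_per_instar(_instar_frame(rng, shift=60.0, n=40))
    assert shifted[Stage.N1].p_value < 0.001
    assert shifted[Stage.N1].p_value < null[Stage.N1].p_value


def test_kruskal_all_tied_and_single_diet():
    frame = pd.DataFrame(
        {
            "stage": [Stage.N1] * 4 + [Stage.N2] * 2,
            "diet": ["Dm", "Dm", "D1", "D1", "Dm", "Dm"],
            "add": [5.0, 5.0, 5.0, 5.0, 1.0, 2.0],
        }
    )
    with pytest.warns(UserWarning, match="fewer than two diets"):
        res = kruskal_wallis_per_instar(frame)
    assert res[Stage.N1].statistic == 0.0 and res[Stage.N1].p_value == 1.0
    assert Stage.N2 not in res


def test_kruskal_accepts_stage_codes():
    frame = pd.DataFrame(
        {"stage": ["N1"] * 6, "diet": ["a", "a", "a", "b", "b", "b"],
         "add": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]}
    )
    res = kruskal_wallis_per_instar(frame)
    assert Stage.N1 in res


# ---------------------------------------------------------------------------
# fecundity two-way ANOVA


def _fecundity_frame(rng, gen_shift=0.0, diet_shift=0.0):
    rows = []
    for diet_i, diet in enumerate(["Dm", "D0", "D1", "D3", "D4"]):
        for gen in (1, 2):
            n = int(rng.integers(10, 16))
            mu = 25 + diet_shift * diet_i + gen_shift * (gen - 1)
            for v in rng.normal(mu, 4, n):
                rows.append({"diet": diet, "generation": gen, "eggs_laid": v})
    return pd.DataFrame(rows)


def test_fecundity_anova_matches_manual_statsmodels():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(21)
    df = _fecundity_frame(rng, gen_shift=6.0)
    res = fecundity_anova(df)
    ref = sm.stats.anova_lm(
        smf.ols("eggs_laid ~ C(diet) + C(generation)", data=df).fit(), typ=2
    )
    assert res.statistic == pytest.approx(float(ref.loc["C(generation)", "F"]))
    assert res.p_value == pytest.approx(float(ref.loc["C(generation)", "PR(>F)"]))
    assert res.extras["F_diet"] == pytest.approx(float(ref.loc["C(diet)", "F"]))
    assert {"lilliefors_p", "levene_p"} <= set(res.extras)


def test_fecundity_detects_generation_effect_only_when_present():
    rng = np.random.default_rng(8)
    with_effect = fecundity_anova(_fecundity_frame(rng, gen_shift=8.0))
    without = fecundity_anova(_fecundity_frame(rng, gen_shift=0.0))
    assert with_effect.p_value < 0.001
    assert with_effect.p_value < without.p_value


def test_fecundity_hatch_rate_response():
    rng = np.random.default_rng(15)
    df = _fecundity_frame(rng)
    df["hatch_rate"] = np.clip(rng.normal(0.95, 0.03, len(df)), 0, 1)
    res = fecundity_anova(df, response="hatch_rate")
    assert 0.0 <= res.p_value <= 1.0


def test_fecundity_degenerate_and_invalid():
    df = pd.DataFrame(
        {"diet": ["a", "a", "b", "b"], "generation": [1, 2, 1, 2],
         "eggs_laid": [5.0, 5.0, 5.0, 5.0]}
    )
    with pytest.raises(DegenerateDataError):
        fecundity_anova(df)
    with pytest.raises(ValueError):
        fecundity_anova(df[df["diet"] == "a"])


def test_fecundity_warns_on_empty_cell():
    rng = np.random.default_rng(4)
    df = _fecundity_frame(rng, gen_shift=2.0)
    df = df[~((df["diet"] == "D4") & (df["generation"] == 2))]
    with pytest.warns(UserWarning, match="empty"):
        fecundity_anova(df)
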