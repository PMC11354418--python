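"""Cohort comparison statistics across diets and generations.

The battery mirrors standard practice for small rearing cohorts:

* sex-ratio homogeneity across diets: Pearson chi-square (no continuity
  correction) with a post hoc on standardized Pearson residuals,
  Bonferroni-adjusted;
* mortality proportions: exact conditional test on the full diets x
  (died, survived) table (Freeman–Halton generalization of Fisher's test,
  by complete enumeration), then pairwise 2x2 exact tests with Bonferroni;
* cumulative degree-days to adulthood: Welch's heteroscedastic ANOVA and
  the Games–Howell pairwise procedure (studentized range with
  Welch–Satterthwaite degrees of freedom);
* per-instar degree-days: Kruskal–Wallis rank test with tie correction;
* fecundity and hatch rate: two-way ANOVA (diet, generation; type-II sums
  of squares), with Lilliefors normality of residuals and Levene
  homogeneity reported alongside.

Welch, Games–Howell, the residual post hoc and the exact r x 2 test are
implemented from closed forms so they can be verified against desk-scale
enumeration oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .stages import Stage

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """The data carry no variation for the requested test."""


@dataclass(frozen=True)
class PosthocResult:
    label: str
    estimate: float  # residual, odds-ratio proxy or mean difference
    p_adjusted: float
    significant: bool
    p_raw: float | None = None


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    posthoc: tuple[PosthocResult, ...] = ()
    extras: Mapping[str, float] = field(default_factory=dict)


def _as_table(counts, index_name: str, columns: Sequence[str]) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    arr = np.asarray(counts)
    return pd.DataFrame(
        arr,
        index=[f"{index_name}{i}" for i in range(arr.shape[0])],
        columns=list(columns),
    )


# ---------------------------------------------------------------------------
# sex ratio


def sex_ratio_test(counts) -> TestResult:
    """Homogeneity of sex composition across diets.

    ``counts``: diets x (male, female) integer table (DataFrame or array).
    Pearson chi-square without continuity correction; df = rows - 1 with two
    sex columns.  The post hoc reports the standardized Pearson residual of
    every cell with a two-sided normal p-value, Bonferroni-adjusted over all
    cells.  Diets with no sexed adults are excluded with a warning.
    """
    tab = _as_table(counts, "diet", ["male", "female"])
    if tab.shape[1] != 2:
        raise ValueError("expected a two-column (male, female) table")
    obs = tab.to_numpy(dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    keep = obs.sum(axis=1) > 0
    if not np.all(keep):
        dropped = list(tab.index[~keep])
        warnings.warn(f"diets with no sexed adults excluded: {dropped}", stacklevel=2)
        tab = tab.loc[keep]
        obs = obs[keep]
    if obs.size == 0 or obs.sum() == 0:
        raise ValueError("all-zero table")
    if obs.shape[0] < 2:
        raise ValueError("need at least two diets")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    # standardized Pearson residuals: (O-E)/sqrt(E (1-row/N)(1-col/N))
    n = obs.sum()
    rowfrac = obs.sum(axis=1, keepdims=True) / n
    colfrac = obs.sum(axis=0, keepdims=True) / n
    denom = np.sqrt(expected * (1 - rowfrac) * (1 - colfrac))
    resid = (obs - expected) / denom
    m = resid.size
    posthoc = []
    for i, diet in enumerate(tab.index):
        for j, sex in enumerate(tab.columns):
            r = float(resid[i, j])
            praw = 2 * sps.norm.sf(abs(r))
            padj = min(1.0, praw * m)
            posthoc.append(
                PosthocResult(f"{diet}:{sex}", r, padj, padj <= ALPHA, praw)
            )
    return TestResult("chi2", float(chi2), float(dof), float(p), tuple(posthoc))


# ---------------------------------------------------------------------------
# exact r x 2 test on mortality

_ENUM_LIMIT = 6_000_000  # grid cells beyond which we fall back to Monte Carlo
_REL_TOL = 1e-7  # tables with prob <= obs * (1 + tol) count toward the p-value


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rx2_logprob_spectrum(n: tuple[int, ...], d_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted log-probabilities of all diets x (died, survived) tables with
    row sums ``n`` and ``d_total`` total deaths, plus their cumulative sums.

    The conditional null is multivariate hypergeometric:
    P(d) = prod_i C(n_i, d_i) / C(N, D).
    """
    n_arr = np.asarray(n, dtype=int)
    caps = np.minimum(d_total, n_arr)
    grid = np.prod(caps[:-1] + 1.0)
    if grid > _ENUM_LIMIT:
        raise MemoryError("enumeration grid too large")
    mesh = np.indices(tuple(caps[:-1] + 1)).reshape(len(n_arr) - 1, -1)
    d_last = d_total - mesh.sum(axis=0)
    valid = (d_last >= 0) & (d_last <= caps[-1])
    mesh = mesh[:, valid]
    d_last = d_last[valid]
    logp = -_log_choose(n_arr.sum(), d_total) + _log_choose(n_arr[-1], d_last)
    for i in range(len(n_arr) - 1):
        logp = logp + _log_choose(n_arr[i], mesh[i])
    order = np.argsort(logp)
    logp = logp[order]
    cum = np.cumsum(np.exp(logp))
    return logp, cum


_spectrum_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _rx2_exact_pvalue(died: np.ndarray, n: np.ndarray, rng=None) -> float:
    """Two-sided exact p-value for an r x 2 table with rows (died, survived).

    Probability-ordering rule: sum the null probabilities of all tables no
    more probable than the observed one (with a 1e-7 relative tie guard),
    as in the classical Freeman–Halton test.  Falls back to seeded Monte
    Carlo when complete enumeration is infeasible.
    """
    died = np.asarray(died, dtype=int)
    n = np.asarray(n, dtype=int)
    d_total = int(died.sum())
    obs_logp = float(
        _log_choose(n, died).sum() - _log_choose(n.sum(), d_total)
    )
    key = (tuple(n.tolist()), d_total)
    try:
        if key not in _spectrum_cache:
            _spectrum_cache[key] = _rx2_logprob_spectrum(tuple(n.tolist()), d_total)
        logp, cum = _spectrum_cache[key]
        idx = np.searchsorted(logp, obs_logp + _REL_TOL, side="right")
        return float(min(1.0, cum[idx - 1])) if idx > 0 else 0.0
    except MemoryError:
        rng = rng or np.random.default_rng(0)
        reps = 100_000
        draws = _sample_rx2(n, d_total, reps, rng)
        logps = (_log_choose(n[None, :], draws).sum(axis=1)
                 - _log_choose(n.sum(), d_total))
        return float((np.sum(logps <= obs_logp + _REL_TOL) + 1) / (reps + 1))


def _sample_rx2(n: np.ndarray, d_total: int, reps: int, rng) -> np.ndarray:
    """Draw death vectors from the multivariate hypergeometric null."""
    out = np.empty((reps, len(n)), dtype=np.int64)
    remaining = np.full(reps, d_total, dtype=np.int64)
    left = int(n.sum())
    for i, ni in enumerate(n[:-1]):
        di = np.where(
            remaining > 0,
            rng.hypergeometric(int(ni), left - int(ni), np.maximum(remaining, 1)),
            0,
        )
        out[:, i] = di
        remaining = remaining - di
        left -= int(ni)
    out[:, -1] = remaining
    return out


def mortality_test(counts, rng=None) -> TestResult:
    """Exact test of mortality proportions across diets.

    ``counts``: diets x (died, survived) table.  The overall p-value comes
    from the exact conditional (Freeman–Halton) test on the full table; the
    post hoc runs every pairwise 2x2 exact test with Bonferroni adjustment.
    """
    tab = _as_table(counts, "diet", ["died", "survived"])
    obs = tab.to_numpy(dtype=int)
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    keep = obs.sum(axis=1) > 0
    if not np.all(keep):
        warnings.warn(
            f"diets with no individuals excluded: {list(tab.index[~keep])}",
            stacklevel=2,
        )
        tab, obs = tab.loc[keep], obs[keep]
    if obs.sum() == 0:
        raise ValueError("all-zero table")
    if obs.shape[0] < 2:
        raise ValueError("need at least two diets")
    n = obs.sum(axis=1)
    p = _rx2_exact_pvalue(obs[:, 0], n, rng=rng)
    pairs = list(combinations(range(obs.shape[0]), 2))
    posthoc = []
    for i, j in pairs:
        sub = obs[[i, j]]
        praw = _rx2_exact_pvalue(sub[:, 0], sub.sum(axis=1), rng=rng)
        padj = min(1.0, praw * len(pairs))
        # difference in death proportions as the effect estimate
        est = sub[0, 0] / sub[0].sum() - sub[1, 0] / sub[1].sum()
        posthoc.append(
            PosthocResult(
                f"{tab.index[i]}-{tab.index[j]}", float(est), padj, padj <= ALPHA, praw
            )
        )
    return TestResult("exact", float("nan"), None, p, tuple(posthoc))


# ---------------------------------------------------------------------------
# Welch ANOVA and Games–Howell


def _group_stats(groups: Sequence[Sequence[float]]):
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    n = np.array([len(g) for g in gs], dtype=float)
    mean = np.array([g.mean() for g in gs])
    var = np.array([g.var(ddof=1) for g in gs])
    return n, mean, var


def welch_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    F* = sum w_i (m_i - m_w)^2 / (k-1) over a correction term, with
    w_i = n_i / s_i^2 and Satterthwaite (fractional) denominator df.  A
    zero-variance group makes the statistic diverge (its mean is known
    exactly); the test then rejects outright unless all data are constant,
    which is a degenerate input.
    """
    n, mean, var = _group_stats(groups)
    k = len(n)
    if np.allclose(np.concatenate([np.asarray(g) for g in groups]),
                   np.asarray(groups[0])[0]):
        raise DegenerateDataError("all observations identical")
    if np.any(var == 0):
        if np.all(var == 0) and len(set(mean)) == 1:
            raise DegenerateDataError("all groups constant and equal")
        return TestResult("F", float("inf"), (float(k - 1), float("inf")), 0.0)
    w = n / var
    mw = np.sum(w * mean) / np.sum(w)
    a = np.sum(w * (mean - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / w.sum()) ** 2 / (n - 1))
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df1 = float(k - 1)
    df2 = float((k**2 - 1) / (3 * lam))
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("F", float(f), (df1, df2), p)


def games_howell(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[TestResult]:
    """Games–Howell pairwise comparisons (unequal variances and sizes).

    For each pair, t = dm / sqrt(s_i^2/n_i + s_j^2/n_j) with
    Welch–Satterthwaite df; the p-value refers q = t * sqrt(2) to the
    studentized range with k groups.
    """
    n, mean, var = _group_stats(groups)
    k = len(n)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    out = []
    for i, j in combinations(range(k), 2):
        se2 = var[i] / n[i] + var[j] / n[j]
        if se2 == 0:
            stat, df, p = (0.0, float(n[i] + n[j] - 2), 1.0) if mean[i] == mean[j] else (
                float("inf"), float(n[i] + n[j] - 2), 0.0)
        else:
            t = (mean[i] - mean[j]) / np.sqrt(se2)
            df = se2**2 / (
                (var[i] / n[i]) ** 2 / (n[i] - 1) + (var[j] / n[j]) ** 2 / (n[j] - 1)
            )
            q = abs(t) * np.sqrt(2)
            p = float(sps.studentized_range.sf(q, k, df))
            stat = float(t)
        out.append(
            TestResult(
                "t",
                stat,
                float(df),
                min(1.0, p),
                (PosthocResult(f"{labels[i]}-{labels[j]}", float(mean[i] - mean[j]),
                               min(1.0, p), p <= ALPHA),),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Kruskal–Wallis per instar


def kruskal_wallis_per_instar(frame: pd.DataFrame) -> dict[Stage, TestResult]:
    """Diet effect on per-stage degree-days, one rank test per instar.

    ``frame`` needs columns ``stage`` (Stage or code), ``diet`` and ``add``.
    H carries the standard tie correction; p from the chi-square
    approximation.  Instars with fewer than two non-empty diets are skipped
    with a warning.
    """
    df = frame.copy()
    if df["stage"].dtype == object and not isinstance(df["stage"].iloc[0], Stage):
        df["stage"] = df["stage"].map(lambda c: Stage[c] if isinstance(c, str) else c)
    out: dict[Stage, TestResult] = {}
    for stage, sub in df.groupby("stage", sort=True):
        groups = [g["add"].to_numpy(float) for _, g in sub.groupby("diet") if len(g)]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            warnings.warn(f"instar {stage}: fewer than two diets with data, skipped",
                          stacklevel=2)
            continue
        if all(np.all(g == groups[0][0]) for g in groups):
            # all observations tied: H = 0 by convention, nothing to rank
            out[Stage(stage)] = TestResult("H", 0.0, float(len(groups) - 1), 1.0)
            continue
        h, p = sps.kruskal(*groups)
        out[Stage(stage)] = TestResult("H", float(h), float(len(groups) - 1), float(p))
    return out


# ---------------------------------------------------------------------------
# fecundity / hatch two-way ANOVA


def fecundity_anova(frame: pd.DataFrame, response: str = "eggs_laid") -> TestResult:
    """Two-way ANOVA of a per-female response on diet and generation.

    ``frame`` needs columns ``diet``, ``generation`` and the response
    (``eggs_laid`` or ``hatch_rate``).  Fits an additive fixed-effects
    model with type-II sums of squares (robust to mild imbalance), and
    reports Lilliefors normality of the residuals and Levene homogeneity
    across diet x generation cells in ``extras``.  The headline statistic
    is the generation effect; the diet effect ships in ``extras``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.diagnostic import lilliefors

    df = frame.dropna(subset=[response]).copy()
    if df["diet"].nunique() < 2 or df["generation"].nunique() < 2:
        raise ValueError("need >= 2 diets and >= 2 generations")
    if np.ptp(df[response].to_numpy(dtype=float)) == 0:
        raise DegenerateDataError("response is constant")
    cells = df.groupby(["diet", "generation"]).size()
    full = df["diet"].nunique() * df["generation"].nunique()
    if len(cells) < full:
        warnings.warn("empty diet x generation cell; type-II SS used", stacklevel=2)
    model = smf.ols(f"{response} ~ C(diet) + C(generation)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_gen = float(table.loc["C(generation)", "F"])
    p_gen = float(table.loc["C(generation)", "PR(>F)"])
    df_gen = (
        float(table.loc["C(generation)", "df"]),
        float(table.loc["Residual", "df"]),
    )
    lil_stat, lil_p = lilliefors(model.resid, dist="norm")
    lev = sps.levene(
        *[g[response].to_numpy(float) for _, g in df.groupby(["diet", "generation"])]
    )
    extras = {
        "F_diet": float(table.loc["C(diet)", "F"]),
        "p_diet": float(table.loc["C(diet)", "PR(>F)"]),
        "df_diet": float(table.loc["C(diet)", "df"]),
        "lilliefors_stat": float(lil_stat),
        "lilliefors_p": float(lil_p),
        "levene_stat": float(lev.statistic),
        "levene_p": float(lev.pvalue),
    }
    return TestResult("F", f_gen, df_gen, p_gen, extras=extras)
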