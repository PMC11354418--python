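"""Null-model calibration harness for the cohort comparison tests.

Draws test inputs directly from the generative families the cohort
simulator uses — binomial sexes and stage deaths, lognormal degree-day
totals — with all diets identical (the null), and measures each test's
rejection rate at a nominal level.  A well-calibrated test rejects a true
null at close to the nominal rate; exact conditional tests are expected to
sit at or below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats as cs


@dataclass(frozen=True)
class CalibrationResult:
    test: str
    n_reps: int
    alpha: float
    rejection_rate: float

    def binomial_bounds(self, z: float = 2.5758293035489004) -> tuple[float, float]:
        """99% binomial band around the nominal level for n_reps trials."""
        half = z * np.sqrt(self.alpha * (1 - self.alpha) / self.n_reps)
        return (self.alpha - half, self.alpha + half)


def _rate(pvals: np.ndarray, alpha: float) -> float:
    return float(np.mean(np.asarray(pvals) <= alpha))


def calibrate_sex_ratio(
    n_reps: int = 2000,
    seed: int = 0,
    n_diets: int = 5,
    adults_per_diet: int = 28,
    male_prob: float = 0.5,
    alpha: float = 0.05,
) -> CalibrationResult:
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_reps):
        males = rng.binomial(adults_per_diet, male_prob, size=n_diets)
        table = np.column_stack([males, adults_per_diet - males])
        ps.append(cs.sex_ratio_test(table).p_value)
    return CalibrationResult("sex_ratio_chi2", n_reps, alpha, _rate(np.array(ps), alpha))


def calibrate_mortality(
    n_reps: int = 2000,
    seed: int = 1,
    n_diets: int = 5,
    cohort_size: int = 33,
    death_prob: float = 0.15,
    alpha: float = 0.05,
) -> CalibrationResult:
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_reps):
        died = rng.binomial(cohort_size, death_prob, size=n_diets)
        table = np.column_stack([died, cohort_size - died])
        ps.append(cs.mortality_test(table).p_value)
    return CalibrationResult("mortality_exact", n_reps, alpha, _rate(np.array(ps), alpha))


def _null_lognormal_groups(rng, n_diets, n_per_diet, mean, cv):
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return [rng.lognormal(mu, np.sqrt(sigma2), size=n_per_diet) for _ in range(n_diets)]


def calibrate_welch(
    n_reps: int = 2000,
    seed: int = 2,
    n_diets: int = 5,
    n_per_diet: int = 28,
    mean: float = 2000.0,
    cv: float = 0.18,
    alpha: float = 0.05,
) -> CalibrationResult:
    rng = np.random.default_rng(seed)
    ps = [
        cs.welch_anova(_null_lognormal_groups(rng, n_diets, n_per_diet, mean, cv)).p_value
        for _ in range(n_reps)
    ]
    return CalibrationResult("welch_anova", n_reps, alpha, _rate(np.array(ps), alpha))


def calibrate_kruskal(
    n_reps: int = 2000,
    seed: int = 3,
    n_diets: int = 5,
    n_per_diet: int = 28,
    mean: float = 350.0,
    cv: float = 0.3,
    alpha: float = 0.05,
) -> CalibrationResult:
    import pandas as pd

    from .stages import Stage

    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_reps):
        groups = _null_lognormal_groups(rng, n_diets, n_per_diet, mean, cv)
        frame = pd.DataFrame(
            {
                "stage": Stage.N1,
                "diet": np.repeat([f"d{i}" for i in range(n_diets)], n_per_diet),
                "add": np.concatenate(groups),
            }
        )
        ps.append(cs.kruskal_wallis_per_instar(frame)[Stage.N1].p_value)
    return CalibrationResult("kruskal_wallis", n_reps, alpha, _rate(np.array(ps), alpha))


def calibrate_all(n_reps: int = 2000, seed: int = 0) -> list[CalibrationResult]:
    return [
        calibrate_sex_ratio(n_reps, seed),
        calibrate_mortality(n_reps, seed + 1),
        calibrate_welch(n_reps, seed + 2),
        calibrate_kruskal(n_reps, seed + 3),
    ]
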