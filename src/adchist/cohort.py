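"""Cohort-level statistics on per-subject brain fractions.

Covers the normative-aging analysis: four age classes ([0,20), [20,40),
[40,60), [60,90]), adjacent-group two-sample t-tests with Bonferroni
correction, and ordinary-least-squares quadratic fits of brain fraction
versus age, y = c0 + c1·x + c2·x², with slope evaluation c1 + 2·c2·x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

AGE_GROUP_BOUNDS = ((0.0, 20.0), (20.0, 40.0), (40.0, 60.0), (60.0, 90.0))
N_ADJACENT_TESTS = 3


@dataclass(frozen=True)
class SubjectResult:
    """One subject's pipeline output: the brain-tissue pixel percentage."""

    subject_id: str
    age: float
    sex: str
    brain_fraction: float
    mask_count: int = 0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.brain_fraction <= 100:
            raise ValueError("brain_fraction must be in [0, 100]")
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class AgeGroupSummary:
    group: int
    bounds: tuple[float, float]
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class GroupComparison:
    pair: tuple[int, int]
    t_statistic: float
    p_raw: float
    p_corrected: float
    n_tests: int


@dataclass(frozen=True)
class QuadraticFit:
    """OLS fit y = c0 + c1·x + c2·x² of brain fraction versus age."""

    c0: float
    c1: float
    c2: float
    rmse: float
    n: int
    stratum: str = "all"

    def predict(self, age):
        age = np.asarray(age, dtype=float)
        out = self.c0 + self.c1 * age + self.c2 * age * age
        return float(out) if out.ndim == 0 else out


def assign_age_group(age: float) -> int:
    """Age-class index 1-4 for [0,20), [20,40), [40,60), [60,90]."""
    if not 0 <= age <= 90:
        raise ValueError("age must be within [0, 90]")
    return int(np.searchsorted([20.0, 40.0, 60.0], age, side="right")) + 1


def group_summary(results: list[SubjectResult]) -> list[AgeGroupSummary]:
    """Per-group n, mean and sample sd (n−1 denominator) of brain fraction.

    Empty groups are reported with n = 0 and NaN mean; sd is NaN when
    n < 2.
    """
    if not results:
        raise ValueError("no subject results")
    summaries = []
    for g, bounds in enumerate(AGE_GROUP_BOUNDS, start=1):
        vals = np.array(
            [r.brain_fraction for r in results if assign_age_group(r.age) == g]
        )
        summaries.append(
            AgeGroupSummary(
                group=g,
                bounds=bounds,
                n=vals.size,
                mean=float(vals.mean()) if vals.size else float("nan"),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            )
        )
    return summaries


def compare_adjacent_groups(
    results: list[SubjectResult], alpha: float = 0.05
) -> list[GroupComparison]:
    """Pooled-variance two-sided t-tests of groups 2v1, 3v2, 4v3.

    Bonferroni-corrected for the family of three adjacent comparisons:
    p_corrected = min(1, 3·p_raw).  ``alpha`` is recorded by callers, not
    used here.
    """
    by_group: dict[int, list[float]] = {g: [] for g in range(1, 5)}
    for r in results:
        by_group[assign_age_group(r.age)].append(r.brain_fraction)
    comparisons = []
    for older, younger in ((2, 1), (3, 2), (4, 3)):
        a = np.asarray(by_group[younger])
        b = np.asarray(by_group[older])
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"group {younger if a.size < 2 else older} has fewer than "
                "2 subjects; cannot test"
            )
        if a.std() == 0 and b.std() == 0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                raise ValueError("zero variance in both groups")
        else:
            t, p = stats.ttest_ind(b, a, equal_var=True)
        comparisons.append(
            GroupComparison(
                pair=(older, younger),
                t_statistic=float(t),
                p_raw=float(p),
                p_corrected=min(1.0, N_ADJACENT_TESTS * float(p)),
                n_tests=N_ADJACENT_TESTS,
            )
        )
    return comparisons


def fit_polynomial(ages: np.ndarray, values: np.ndarray,
                   stratum: str = "all") -> QuadraticFit:
    """Degree-2 OLS fit from raw arrays; used by fit_quadratic."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError(
            "quadratic fit requires at least 3 subjects with 3 distinct ages"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, 2)
    resid = y - (coeffs[0] + coeffs[1] * x + coeffs[2] * x * x)
    return QuadraticFit(
        c0=float(coeffs[0]),
        c1=float(coeffs[1]),
        c2=float(coeffs[2]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=int(x.size),
        stratum=stratum,
    )


def fit_quadratic(results: list[SubjectResult],
                  stratum: str = "all") -> QuadraticFit:
    """Quadratic age-trajectory fit over all subjects or one sex stratum."""
    if stratum not in ("all", "female", "male"):
        raise ValueError("stratum must be 'all', 'female' or 'male'")
    sel = [r for r in results if stratum == "all" or r.sex == stratum]
    ages = np.array([r.age for r in sel])
    vals = np.array([r.brain_fraction for r in sel])
    return fit_polynomial(ages, vals, stratum=stratum)


def slope_at_age(fit: QuadraticFit, age: float) -> float:
    """Derivative c1 + 2·c2·age of the fitted trajectory, %/year."""
    return float(fit.c1 + 2.0 * fit.c2 * age)
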