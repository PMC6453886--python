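"""Shared statistical primitives.

Every downstream stage (screen hit calling, lipid differential abundance,
curve-shift testing, lineage selectivity) funnels its inference through the
small set of tests defined here, so that each can be validated once against
brute-force oracles and reused everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "student_t_test",
    "mann_whitney_u",
    "bh_adjust",
    "robust_z",
    "EXACT_MW_MAX_N",
]

#: largest combined sample size for which the Mann-Whitney U p-value is
#: computed by exact enumeration of the null distribution (ties always fall
#: back to the normal approximation, where exact enumeration is invalid).
EXACT_MW_MAX_N = 12

# MAD -> sigma consistency constant for the normal distribution (1/Phi^-1(3/4))
_MAD_SCALE = 1.4826022185056018


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")


def student_t_test(
    group_a,
    group_b,
    two_sided: bool = True,
    equal_var: bool = True,
) -> TestResult:
    """Two-sample t-test (Student's pooled-variance form by default).

    Parameters
    ----------
    group_a, group_b
        Numeric sequences, each with at least two values.
    two_sided
        If False, the alternative is mean(a) > mean(b).
    equal_var
        Pooled-variance Student test when True; Welch's test when False.

    Returns
    -------
    TestResult
        Statistic and p-value from the t distribution with n1+n2-2 degrees
        of freedom (Welch-Satterthwaite df when ``equal_var=False``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("student_t_test requires >= 2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")

    # Degenerate case: no variance anywhere and equal means.
    if np.var(a) == 0.0 and np.var(b) == 0.0 and a.mean() == b.mean():
        return TestResult(0.0, 1.0, "student_t", a.size, b.size)

    alternative = "two-sided" if two_sided else "greater"
    res = _sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    method = "student_t" if equal_var else "welch_t"
    return TestResult(float(res.statistic), float(res.pvalue), method, a.size, b.size)


def mann_whitney_u(group_a, group_b, two_sided: bool = True) -> TestResult:
    """Mann-Whitney-Wilcoxon rank-sum test.

    The U statistic is reported for ``group_a``.  The p-value is exact (full
    enumeration of the rank-configuration null) when n1+n2 <= 12 and there
    are no ties; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u requires non-empty groups")

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size <= EXACT_MW_MAX_N) and not has_ties
    alternative = "two-sided" if two_sided else "greater"
    res = _sps.mannwhitneyu(
        a,
        b,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    method = "mann_whitney_exact" if exact else "mann_whitney_normal"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method, a.size, b.size)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    With order statistics p_(1) <= ... <= p_(m), the adjusted value for
    rank i is min_{j >= i} (m/j) * p_(j), capped at 1, and results are
    returned in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def robust_z(values) -> np.ndarray:
    """Robust z-scores: (x - median) / (1.4826 * MAD).

    The 1.4826 factor makes the MAD a consistent estimator of the standard
    deviation under normality, so the scores are comparable to ordinary
    z-scores when most observations follow the null.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("robust_z requires at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        raise ValueError(
            "MAD is zero; fall back to a standard-deviation z-score "
            "(the robust scale is undefined for this input)"
        )
    return (x - med) / (_MAD_SCALE * mad)
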