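"""Statistical tests shared across the pipeline.

Thin, contract-enforcing wrappers around scipy.stats: two-sided Mann-Whitney
U (normal approximation with tie and continuity correction), Pearson
chi-square without continuity correction, Fisher's exact test on 2x2 tables,
and the pooled-variance two-sample t-test.  All tests are two-sided and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    exact: bool = False


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U, normal approximation with tie correction and
    continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("mann_whitney needs at least 2 observations per sample")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney-u")


def chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c contingency table, df = (r-1)(c-1),
    no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise StatsError("table must be a 2-D nonnegative array")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("chi_square: table has a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(p), "pearson-chi-square", df=float(dof))


def fisher_exact(table2x2) -> TestResult:
    """Two-sided Fisher exact test (hypergeometric tail summation)."""
    t = np.asarray(table2x2)
    if t.shape != (2, 2) or (t < 0).any():
        raise StatsError("fisher_exact needs a nonnegative 2x2 table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact", exact=True)


def t_test(x, y) -> TestResult:
    """Two-sided pooled-variance (Student) t-test.

    Degenerate zero-variance inputs follow the natural limits: equal means
    give p = 1, unequal means p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("t_test needs at least 2 observations per sample")
    df = len(x) + len(y) - 2
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "student-t", df=float(df))
        return TestResult(float("inf"), 0.0, "student-t", df=float(df))
    res = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(res.statistic), float(res.pvalue), "student-t", df=float(df))
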