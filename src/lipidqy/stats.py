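"""One-way ANOVA and the two-sample variance F-test, from first principles.

These are the two comparisons used to assess lipid-content measurements:
ANOVA for equality of group means (significance threshold 0.05) and the
variance-ratio F-test for equality of group variances (default level 0.10,
i.e. a 90% confidence standard).  Statistics are computed directly from sums
of squares; F-distribution tail probabilities come from the regularized
incomplete beta function:

    P(F > f | d1, d2) = I_{d2 / (d2 + d1 f)}(d2/2, d1/2)

Independent implementations (scipy.stats) serve as cross-checks in the test
suite, never as the computation here.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import betainc

from .errors import InsufficientDataError, UndefinedStatisticError

__all__ = [
    "GroupedMeasurements",
    "TestResult",
    "f_sf",
    "one_way_anova",
    "variance_f_test",
    "write_results_table",
]


@dataclass(frozen=True)
class GroupedMeasurements:
    """Labelled numeric samples, e.g. lipid % w/w per replicate per condition."""

    groups: tuple  # of float tuples
    labels: tuple  # of str

    @classmethod
    def from_lists(cls, groups: Sequence[Sequence[float]],
                   labels: Sequence[str] | None = None) -> "GroupedMeasurements":
        if labels is None:
            labels = [f"group{i + 1}" for i in range(len(groups))]
        if len(labels) != len(groups):
            raise ValueError("labels and groups must have equal length")
        return cls(tuple(tuple(float(x) for x in g) for g in groups), tuple(labels))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: tuple  # (df1, df2)
    p_value: float
    level: float
    significant: bool
    test: str = ""


def f_sf(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution via the regularized
    incomplete beta function."""
    if math.isinf(f):
        return 0.0
    if f <= 0:
        return 1.0
    return float(betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * f)))


def one_way_anova(data: GroupedMeasurements, level: float = 0.05) -> TestResult:
    """Parametric one-way analysis of variance for equality of group means.

    F is the ratio of the between-group mean square to the within-group mean
    square, on (k - 1, n - k) degrees of freedom.  Equal within-group values
    with unequal means yield an infinite F (p = 0, flagged significant); all
    observations identical leaves the statistic undefined.
    """
    groups = [np.asarray(g, dtype=float) for g in data.groups]
    k = len(groups)
    if k < 2:
        raise InsufficientDataError("ANOVA needs at least 2 groups")
    if any(g.size < 1 for g in groups):
        raise InsufficientDataError("every group needs at least one observation")
    n = sum(g.size for g in groups)
    if n <= k:
        raise InsufficientDataError(
            f"total observations ({n}) must exceed the number of groups ({k})"
        )
    grand = float(np.concatenate(groups).mean())
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise UndefinedStatisticError(
                "all observations identical: F statistic undefined"
            )
        # groups internally constant but means differ: infinite F
        return TestResult(statistic=math.inf, df=(df1, df2), p_value=0.0,
                          level=level, significant=True, test="one-way ANOVA")
    f = (ssb / df1) / (ssw / df2)
    p = f_sf(f, df1, df2)
    return TestResult(statistic=float(f), df=(df1, df2), p_value=p,
                      level=level, significant=p < level, test="one-way ANOVA")


def variance_f_test(group_a: Sequence[float], group_b: Sequence[float],
                    level: float = 0.10, two_sided: bool = True) -> TestResult:
    """Variance-ratio F-test for equality of two group variances.

    F = s_a^2 / s_b^2 on (n_a - 1, n_b - 1) degrees of freedom.  The
    two-sided p-value doubles the smaller tail (capped at 1); the one-sided
    alternative tests var_a > var_b.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va == 0.0 or vb == 0.0:
        raise UndefinedStatisticError("zero sample variance: F statistic undefined")
    f = va / vb
    df1, df2 = a.size - 1, b.size - 1
    upper = f_sf(f, df1, df2)
    if two_sided:
        p = min(1.0, 2.0 * min(upper, 1.0 - upper))
    else:
        p = upper
    return TestResult(statistic=f, df=(df1, df2), p_value=p,
                      level=level, significant=p < level, test="variance F-test")


def write_results_table(results: Sequence[tuple[str, TestResult]],
                        path: str | os.PathLike) -> None:
    """Write labelled test results as a CSV table."""
    lines = ["comparison,test,statistic,df1,df2,p_value,level,significant"]
    for name, r in results:
        lines.append(
            f"{name},{r.test},{r.statistic:.10g},{r.df[0]},{r.df[1]},"
            f"{r.p_value:.10g},{r.level:g},{str(r.significant).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
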