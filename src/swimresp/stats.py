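"""Two-group comparisons and outlier screens used on the trait tables.

Welch's t (unequal variances, Welch-Satterthwaite df) compares the two
temperature groups; a paired t compares rest against the 2-h recovery point.
Grubbs' test and Rosner's generalized extreme studentized deviate (ESD) screen
each dataset for outliers before comparison; both are implemented from their
t-distribution closed forms since neither ships with scipy.  All tests are
two-sided with alpha = 0.05 by default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import InsufficientDataError
from .types import TestResult

ALPHA = 0.05


def welch_t(group_a, group_b) -> TestResult:
    """Welch's two-sample t-test (two-sided).

    Zero variance in both groups with equal means returns t = 0, p = 1 by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate limit: identical constants -> p = 1; separated
        # constants -> p = 0
        if a.mean() == b.mean():
            return TestResult(0.0, float(a.size + b.size - 2), 1.0,
                              "welch_t", a.size, b.size)
        stat = np.inf if a.mean() > b.mean() else -np.inf
        return TestResult(float(stat), float(a.size + b.size - 2), 0.0,
                          "welch_t", a.size, b.size)
    res = sstats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      "welch_t", a.size, b.size)


def paired_t(before, after) -> TestResult:
    """Paired t-test: one-sample t on the differences, two-sided."""
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("paired samples must have equal length")
    if x.size < 2:
        raise InsufficientDataError("need n >= 2 pairs")
    d = y - x
    if np.ptp(d) == 0:
        # constant differences: no change -> p = 1; uniform shift -> p = 0
        if d[0] == 0:
            return TestResult(0.0, float(x.size - 1), 1.0, "paired_t",
                              x.size, x.size)
        stat = np.inf if d[0] > 0 else -np.inf
        return TestResult(float(stat), float(x.size - 1), 0.0, "paired_t",
                          x.size, x.size)
    res = sstats.ttest_rel(y, x)
    return TestResult(float(res.statistic), float(x.size - 1), float(res.pvalue),
                      "paired_t", x.size, x.size)


@dataclass(frozen=True)
class GrubbsResult:
    g: float
    g_critical: float
    outlier_index: int | None
    is_outlier: bool
    n: int


def grubbs_critical(n: int, alpha: float = ALPHA) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t = sstats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values, alpha: float = ALPHA) -> GrubbsResult:
    """Grubbs' test for a single outlier (two-sided, sample SD).

    G = max|x - mean| / sd; constant data contain no outlier by definition.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("Grubbs' test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return GrubbsResult(0.0, grubbs_critical(x.size, alpha), None, False, x.size)
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / sd)
    g_crit = float(grubbs_critical(x.size, alpha))
    return GrubbsResult(g, g_crit, i if g > g_crit else None, g > g_crit, x.size)


@dataclass(frozen=True)
class RosnerResult:
    flagged_indices: list[int]
    r_statistics: list[float]
    lambdas: list[float]
    candidate_indices: list[int]


def rosner_esd(values, k_max: int, alpha: float = ALPHA) -> RosnerResult:
    """Rosner's generalized ESD test for up to ``k_max`` outliers.

    Iteratively removes the most extreme point, computing R_i and its
    critical value lambda_i; the largest i with R_i > lambda_i determines
    the number of outliers (all more-extreme points are flagged with it).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        warnings.warn("Rosner's test is recommended for n >= 10", stacklevel=2)
    if not (0 < k_max < n / 2):
        raise InsufficientDataError("require 0 < k_max < n/2")
    remaining = list(range(n))
    r_stats: list[float] = []
    lambdas: list[float] = []
    candidates: list[int] = []
    for i in range(1, k_max + 1):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        r_stats.append(float(dev[j] / sd))
        candidates.append(remaining[j])
        m = n - i + 1  # points in the current subsample
        p = 1.0 - alpha / (2.0 * m)
        t = sstats.t.ppf(p, m - 2)
        lambdas.append(float((m - 1) * t / np.sqrt((m - 2 + t**2) * m)))
        del remaining[j]
    n_out = 0
    for i, (r, lam) in enumerate(zip(r_stats, lambdas), start=1):
        if r > lam:
            n_out = i
    return RosnerResult(candidates[:n_out], r_stats, lambdas, candidates)


def assumption_checks(*groups) -> dict:
    """Normality (Shapiro-Wilk, per group) and variance homogeneity (Levene).

    Assumption screens only — they gate nothing in the pipeline's outputs;
    internals are delegated to scipy.
    """
    out = {
        "shapiro_p": [float(sstats.shapiro(np.asarray(g, float)).pvalue)
                      for g in groups],
    }
    if len(groups) >= 2:
        out["levene_p"] = float(sstats.levene(*[np.asarray(g, float)
                                                for g in groups]).pvalue)
    return out
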