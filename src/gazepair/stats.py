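"""Descriptive and inferential conventions used throughout the analyses.

All reported data are medians and boxplots, so the inferential toolkit is
nonparametric: Kruskal-Wallis tests across conditions with an eta-squared
effect size obtained via an F transform, Wilcoxon signed-rank tests
between conditions with the paired-dominance effect size PS_dep (the
proportion of positive paired differences), and seeded percentile
bootstraps for interval estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedMetricError


@dataclass(frozen=True)
class BoxplotStats:
    """The quantities a standard Tukey boxplot draws.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme data points within 1.5 iqr of the box, and
    values beyond the whiskers are listed individually as outliers.
    """

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    effect_size: float
    n: int


def boxplot_stats(values) -> BoxplotStats:
    """Median, quartiles, whisker ends, and outliers of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise UndefinedMetricError("boxplot of an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]))
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=outliers,
    )


def psdep(x, y) -> float:
    """Paired-dominance effect size: proportion of positive differences.

    Counts strictly positive values of ``x - y`` over all N pairs,
    including ties (zero differences) in the denominator.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size == 0:
        raise UndefinedMetricError("PS_dep of empty samples")
    return float(np.mean(d > 0))


def wilcoxon_psdep(x, y) -> TestResult:
    """Wilcoxon signed-rank test with the PS_dep effect size.

    Zero differences are dropped from the test (mid-ranks for tied
    magnitudes); the p value comes from exact enumeration for up to 25
    non-zero untied differences and from the normal approximation with
    continuity correction otherwise. If every difference is zero the test
    is undefined (NaN statistic and p) and PS_dep is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UndefinedMetricError("paired samples must have equal length")
    effect = psdep(x, y)
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(float("nan"), float("nan"), effect, int(d.size))
    has_ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, method=method, correction=(method == "approx"))
    return TestResult(float(res.statistic), float(res.pvalue), effect, int(d.size))


def kruskal_eta2(*groups) -> TestResult:
    """Kruskal-Wallis test with eta-squared via the F transform.

    H is tie-corrected; p comes from the chi-square reference with
    ``k - 1`` df. The effect size transforms H to an F value as the
    ``1 - p`` quantile of ``F(k - 1, N - k)`` and computes
    ``eta^2 = F df1 / (F df1 + df2)``. With all values tied H = 0 and
    eta^2 = 0. If ``N - k`` is not positive, eta^2 is undefined (NaN).
    """
    if len(groups) < 2:
        raise UndefinedMetricError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise UndefinedMetricError("Kruskal-Wallis got an empty group")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df1, df2 = k - 1, n_total - k
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # All values identical: no rank variation at all.
        return TestResult(0.0, 1.0, 0.0, n_total)
    h, p = sps.kruskal(*arrays)
    if df2 <= 0:
        return TestResult(float(h), float(p), float("nan"), n_total)
    f = sps.f.ppf(1.0 - p, df1, df2)
    eta2 = (f * df1) / (f * df1 + df2) if np.isfinite(f) else 1.0
    return TestResult(float(h), float(p), float(eta2), n_total)


def percentile_bootstrap(
    values,
    statistic: Callable = np.mean,
    n_boot: int = 1000,
    seed=0,
    ci: float = 95.0,
):
    """Seeded percentile bootstrap of an arbitrary statistic.

    Resamples the observations (rows, for 2-D input) with replacement
    ``n_boot`` times and returns ``(estimate, (lo, hi))`` with the
    2.5 / 97.5 percentile endpoints for a 95% interval.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise UndefinedMetricError("bootstrap of an empty sample")
    rng = np.random.default_rng(seed)
    n = v.shape[0]
    reps = np.array([statistic(v[rng.integers(0, n, size=n)]) for _ in range(n_boot)])
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(reps, [alpha, 100.0 - alpha], axis=0)
    return statistic(v), (lo, hi)


def comparison_table(rows: Sequence[dict]) -> "pandas.DataFrame":
    """Assemble test results into the reporting-style table.

    ``rows`` are dicts with keys ``comparison``, ``test`` and a
    :class:`TestResult` under ``result``.
    """
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "comparison": r["comparison"],
                "test": r["test"],
                "statistic": r["result"].statistic,
                "p_value": r["result"].p_value,
                "effect_size": r["result"].effect_size,
                "n": r["result"].n,
            }
            for r in rows
        ]
    )
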