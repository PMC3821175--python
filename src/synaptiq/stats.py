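"""Group statistics: mean +- SEM, two-tailed t tests, one-way ANOVA with
Student-Newman-Keuls (SNK) post hoc comparisons.

The SNK procedure orders the group means, computes studentized-range
statistics for every pair, and applies the step-down containment rule: a
pair is declared different at level alpha only if its range statistic
exceeds the span-dependent critical value *and* every enclosing range is
also significant.  Critical values come from the studentized-range
distribution computed numerically, so arbitrary group sizes are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["DescribeResult", "TestResult", "describe", "t_test", "anova_snk"]


@dataclass
class DescribeResult:
    mean: float
    sem: float   # NaN (flagged) when n == 1
    n: int
    sd: float

    @property
    def sem_defined(self) -> bool:
        return self.n > 1


def describe(values) -> DescribeResult:
    """Mean, SEM (sample SD / sqrt(n)) and n of one group."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty group")
    if vals.size == 1:
        return DescribeResult(float(vals[0]), math.nan, 1, math.nan)
    sd = float(vals.std(ddof=1))
    return DescribeResult(float(vals.mean()), sd / math.sqrt(vals.size),
                          int(vals.size), sd)


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float
    p_value: float
    pairwise: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)


def t_test(a, b, paired: bool = False, welch: bool = False) -> TestResult:
    """Two-tailed Student's t test (pooled variance unless ``welch``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size or a.size < 2:
            raise ValueError("paired test needs equal lengths >= 2")
        diff = a - b
        if diff.std(ddof=1) == 0:
            raise ValueError("degenerate variance of paired differences")
        res = sps.ttest_rel(a, b)
        return TestResult("paired t", float(res.statistic), float(res.df),
                          float(res.pvalue))
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired test needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    name = "welch t" if welch else "student t"
    return TestResult(name, float(res.statistic), float(res.df),
                      float(res.pvalue))


def anova_snk(
    groups: dict, alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
) -> TestResult:
    """One-way ANOVA with SNK stepwise pairwise comparisons.

    ``groups`` maps label -> 1-D measurements.  Returns the ANOVA F and p
    plus ``pairwise[(label_i, label_j)][alpha] = bool`` decisions.
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    for g, d in zip(labels, data):
        if d.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2")

    f_stat, p = sps.f_oneway(*data)
    k = len(data)
    ns = np.array([d.size for d in data])
    means = np.array([d.mean() for d in data])
    df_w = int(ns.sum() - k)
    msw = sum((d.size - 1) * d.var(ddof=1) for d in data) / df_w

    # sort by mean (stable on ties so results are input-order invariant)
    order = np.lexsort((np.arange(k), means))
    s_means = means[order]
    s_ns = ns[order]
    s_labels = [labels[i] for i in order]

    pairwise: dict = {}
    q_stats: dict = {}
    for alpha in alphas:
        sig = {}
        # decreasing span so the containment rule can consult parents
        for span in range(k, 1, -1):
            qcrit = float(sps.studentized_range.ppf(1 - alpha, span, df_w))
            for i in range(0, k - span + 1):
                j = i + span - 1
                se = math.sqrt(msw / 2.0 * (1.0 / s_ns[i] + 1.0 / s_ns[j]))
                q = (s_means[j] - s_means[i]) / se if se > 0 else math.inf
                q_stats[(i, j)] = q
                parents = [p_ for p_ in ((i - 1, j), (i, j + 1))
                           if 0 <= p_[0] and p_[1] <= k - 1]
                blocked = any(not sig[p_] for p_ in parents)
                sig[(i, j)] = (q > qcrit) and not blocked
        for (i, j), s in sig.items():
            key = (s_labels[i], s_labels[j])
            pairwise.setdefault(key, {})[alpha] = bool(s)

    return TestResult(
        "one-way ANOVA + SNK", float(f_stat), float(k - 1), float(p),
        pairwise=pairwise,
        details={"df_within": df_w, "ms_within": float(msw),
                 "group_means": dict(zip(labels, means.tolist())),
                 "q_statistics": {f"{s_labels[i]}|{s_labels[j]}": q
                                  for (i, j), q in q_stats.items()}},
    )
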