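"""Gated parametric/nonparametric group comparisons and categorical tests.

The decision tree for pairwise comparisons: Shapiro-Wilk normality test on
each sample (alpha 0.05); if either is non-normal, a two-sided
Mann-Whitney U test; otherwise an F-test for equal variances routes to a
standard Student's t-test (homoscedastic) or Welch's t-test
(heteroscedastic).  Multi-group comparisons are gated the same way into
one-way ANOVA with Bonferroni-adjusted pairwise t post hoc tests, or a
Kruskal-Wallis test with Bonferroni-adjusted pairwise Mann-Whitney tests.
Categorical distributions are compared with Pearson's chi-squared test
(no continuity correction).  Significance is reported in three categories
(* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StatResult",
    "compare_two_groups",
    "compare_multi_groups",
    "chi_squared_distribution",
    "bonferroni",
    "significance_category",
]

STUDENT_T = "STUDENT_T"
WELCH_T = "WELCH_T"
MANN_WHITNEY = "MANN_WHITNEY"
ANOVA_BONF = "ANOVA_BONF"
KRUSKAL = "KRUSKAL"
CHI2 = "CHI2"
PAIRWISE_BONF = "PAIRWISE_BONF"


def significance_category(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class StatResult:
    test_used: str
    statistic: float
    p: float
    significance: str
    #: record of the gating pre-tests (normality / variance) that chose the test
    decisions: dict = field(default_factory=dict)
    #: pairwise post hoc results for multi-group comparisons
    pairwise: list["StatResult"] = field(default_factory=list)


def _shapiro_normal(x: np.ndarray, alpha: float) -> tuple[bool, float]:
    """(is_normal, p).  Constant samples have undefined normality -> (False, nan)."""
    if np.ptp(x) == 0:
        return False, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.shapiro(x).pvalue)
    return p >= alpha, p


def _f_test_equal_var(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test of equal variances; returns (F, p)."""
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vy == 0 and vx == 0:
        return 1.0, 1.0
    if vy == 0 or vx == 0:
        return float("inf"), 0.0
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    cdf = stats.f.cdf(f, dfx, dfy)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), float(min(p, 1.0))


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else
    normal approximation with tie correction."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(
    x: Sequence[float], y: Sequence[float], alpha_norm: float = 0.05
) -> StatResult:
    """Compare two independent samples through the gated decision tree."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    nx_ok, px = _shapiro_normal(x, alpha_norm)
    ny_ok, py = _shapiro_normal(y, alpha_norm)
    decisions = {"shapiro_p": (px, py), "normal": (nx_ok, ny_ok)}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant sample: normality undefined, using Mann-Whitney")
    if not (nx_ok and ny_ok):
        stat, p = _mannwhitney(x, y)
        test = MANN_WHITNEY
    else:
        f, pf = _f_test_equal_var(x, y)
        equal_var = pf >= alpha_norm
        decisions["f_test"] = {"F": f, "p": pf, "equal_var": equal_var}
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
        test = STUDENT_T if equal_var else WELCH_T
    return StatResult(
        test_used=test,
        statistic=stat,
        p=p,
        significance=significance_category(p),
        decisions=decisions,
    )


def compare_multi_groups(
    groups: Sequence[Sequence[float]], alpha_norm: float = 0.05
) -> StatResult:
    """Omnibus + Bonferroni-adjusted pairwise comparison of >= 3 groups.

    Normality of every group (Shapiro-Wilk) and homoscedasticity (Bartlett,
    the multi-sample analogue of the two-sample F-test) gate the route:
    one-way ANOVA with pairwise t post hoc tests, or Kruskal-Wallis with
    pairwise Mann-Whitney tests; pairwise p-values are Bonferroni-adjusted.
    With two groups the call falls through to :func:`compare_two_groups`.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 3:
        if len(arrs) == 2:
            return compare_two_groups(arrs[0], arrs[1], alpha_norm)
        raise ValueError("need at least 2 groups")
    if any(len(a) < 3 for a in arrs):
        raise ValueError("each group needs n >= 3")

    norm = [_shapiro_normal(a, alpha_norm) for a in arrs]
    all_normal = all(ok for ok, _ in norm)
    decisions = {"shapiro_p": [p for _, p in norm], "normal": [ok for ok, _ in norm]}
    parametric = False
    if all_normal:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bart = stats.bartlett(*arrs)
        homosc = bart.pvalue >= alpha_norm
        decisions["bartlett"] = {"stat": float(bart.statistic), "p": float(bart.pvalue)}
        parametric = homosc

    m = len(arrs) * (len(arrs) - 1) // 2
    pairwise: list[StatResult] = []
    if parametric:
        omni = stats.f_oneway(*arrs)
        test = ANOVA_BONF
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                r = stats.ttest_ind(arrs[i], arrs[j], equal_var=True)
                p_adj = min(1.0, float(r.pvalue) * m)
                pairwise.append(
                    StatResult(
                        STUDENT_T,
                        float(r.statistic),
                        p_adj,
                        significance_category(p_adj),
                        decisions={"pair": (i, j), "raw_p": float(r.pvalue)},
                    )
                )
    else:
        omni = stats.kruskal(*arrs)
        test = KRUSKAL
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                s, praw = _mannwhitney(arrs[i], arrs[j])
                p_adj = min(1.0, praw * m)
                pairwise.append(
                    StatResult(
                        MANN_WHITNEY,
                        s,
                        p_adj,
                        significance_category(p_adj),
                        decisions={"pair": (i, j), "raw_p": praw},
                    )
                )
    p = float(omni.pvalue)
    return StatResult(
        test_used=test,
        statistic=float(omni.statistic),
        p=p,
        significance=significance_category(p),
        decisions=decisions,
        pairwise=pairwise,
    )


def chi_squared_distribution(table: np.ndarray) -> StatResult:
    """Pearson's chi-squared test of independence on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatResult(
        test_used=CHI2,
        statistic=float(chi2),
        p=float(p),
        significance=significance_category(float(p)),
        decisions={"dof": int(dof)},
    )


def bonferroni(pvals: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    pvals = list(pvals)
    if any(not (0.0 <= p <= 1.0) for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals)
    return [min(1.0, p * m) for p in pvals]
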