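"""Normality-gated group comparisons and exact tests.

The comparison protocol: Shapiro-Wilk normality tests gate the choice of
test family. If every group is consistent with normality, means are compared
with Welch's t-test (two groups) or Welch's ANOVA (three or more, robust to
unequal variances); otherwise Mann-Whitney (two groups) or Kruskal-Wallis
(three or more). Capture frequencies are compared with Fisher's exact test.
P-values are reported raw (no multiple-testing correction) with the
significance-star convention * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupedSamples:
    """Named groups of numeric observations for one metric."""

    groups: dict[str, np.ndarray]
    metric_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least two groups to compare")
        for name, vals in self.groups.items():
            if vals.size < 1:
                raise ValueError(f"group {name!r} is empty")

    def values(self) -> list[np.ndarray]:
        return list(self.groups.values())


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    normality_gate_used: Optional[dict[str, bool]] = None
    p_one_sided: Optional[float] = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _group_is_normal(vals: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk at ``alpha``; groups too small or constant fail the gate."""
    if vals.size < 3 or np.ptp(vals) == 0:
        return False
    _, p = sps.shapiro(vals)
    return bool(p > alpha)


def normality_gate(groups: GroupedSamples, alpha: float = 0.05) -> str:
    """'parametric' iff every group passes Shapiro-Wilk at ``alpha``."""
    ok = all(_group_is_normal(v, alpha) for v in groups.values())
    return "parametric" if ok else "nonparametric"


def welch_anova(samples: Sequence[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F*, p).

    Welch (1951): groups are weighted by n/s²; the F statistic is referred to
    an F distribution with adjusted denominator degrees of freedom.
    """
    k = len(samples)
    n = np.array([len(s) for s in samples], dtype=float)
    m = np.array([np.mean(s) for s in samples])
    v = np.array([np.var(s, ddof=1) for s in samples])
    if np.any(v == 0):
        raise ZeroDivisionError("a group has zero variance")
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    b = 1.0 + (2.0 * (k - 2) / (k ** 2 - 1)) * np.sum(
        (1 - w / np.sum(w)) ** 2 / (n - 1)
    )
    f = a / b
    df2 = (k ** 2 - 1) / (3.0 * np.sum((1 - w / np.sum(w)) ** 2 / (n - 1)))
    p = float(sps.f.sf(f, k - 1, df2))
    return float(f), p


def mann_whitney(a, b) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U: (U, p, method).

    Exact enumeration when both n ≤ 8 with no ties, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size <= 8 and b.size <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(res.pvalue), method


def compare_groups(groups: GroupedSamples, alpha: float = 0.05) -> TestResult:
    """Gate on normality and dispatch to the appropriate comparison.

    Two groups → Welch's t or Mann-Whitney; three or more → Welch's ANOVA or
    Kruskal-Wallis (tie-corrected chi-square approximation). A zero-variance
    group in the parametric branch falls back to the nonparametric test with
    a warning note.
    """
    vals = groups.values()
    gate = {name: _group_is_normal(v, alpha) for name, v in groups.groups.items()}
    branch = "parametric" if all(gate.values()) else "nonparametric"
    note = ""

    if branch == "parametric" and any(np.var(v, ddof=1) == 0 for v in vals):
        branch = "nonparametric"
        note = "zero-variance group: fell back to nonparametric test"

    if len(vals) == 2:
        a, b = vals
        if branch == "parametric":
            res = sps.ttest_ind(a, b, equal_var=False)
            return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                              alpha, gate, note=note)
        stat, p, method = mann_whitney(a, b)
        return TestResult(f"mann_whitney_{method}", stat, p, alpha, gate, note=note)

    if branch == "parametric":
        f, p = welch_anova(vals)
        return TestResult("welch_anova", f, p, alpha, gate, note=note)
    stat, p = sps.kruskal(*vals)
    return TestResult("kruskal_wallis", float(stat), float(p), alpha, gate, note=note)


def brown_forsythe(groups: GroupedSamples, alpha: float = 0.05) -> TestResult:
    """Brown-Forsythe test of equal variances: ANOVA on absolute deviations
    from group medians. Identical constant groups give statistic 0, p 1."""
    vals = groups.values()
    if all(np.ptp(v) == 0 for v in vals):
        return TestResult("brown_forsythe", 0.0, 1.0, alpha)
    stat, p = sps.levene(*vals, center="median")
    return TestResult("brown_forsythe", float(stat), float(p), alpha)


def fisher_exact(table: Sequence[Sequence[int]], alpha: float = 0.05) -> TestResult:
    """Fisher's exact test on a 2×2 contingency table.

    Two-sided p is the probability-mass convention (sum over tables at most
    as probable as the observed one); the smaller directional p is reported
    as ``p_one_sided``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(int)
    _, p_two = sps.fisher_exact(t, alternative="two-sided")
    _, p_greater = sps.fisher_exact(t, alternative="greater")
    _, p_less = sps.fisher_exact(t, alternative="less")
    odds = sps.fisher_exact(t)[0]
    return TestResult("fisher_exact", float(odds), float(p_two), alpha,
                      p_one_sided=float(min(p_greater, p_less)))


def report_comparisons(
    grouped: Sequence[GroupedSamples], alpha: float = 0.05
):
    """Run compare_groups over several metrics and return a tidy DataFrame."""
    import pandas as pd

    rows = []
    for gs in grouped:
        res = compare_groups(gs, alpha)
        rows.append({
            "metric": gs.metric_name,
            "units": gs.units,
            "groups": ",".join(gs.groups),
            "test": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "stars": significance_stars(res.p_value),
            "normality_gate": ";".join(
                f"{k}={'N' if v else 'not-N'}" for k, v in (res.normality_gate_used or {}).items()
            ),
            "note": res.note,
        })
    return pd.DataFrame(rows)
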