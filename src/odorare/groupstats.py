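"""Nonparametric comparison of observation counts across rarity groups.

Citizen-science observation counts per species are heavily skewed, so the
group-comparison pipeline is: Shapiro-Wilk as a normality gate, a
Kruskal-Wallis omnibus test across groups, then pairwise two-sided
Wilcoxon rank-sum tests with Bonferroni correction.  Statistics delegate
to scipy.stats; the Kruskal-Wallis H is additionally unit-tested against a
hand rank computation elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedCounts",
    "shapiro_wilk",
    "kruskal_wallis",
    "pairwise_wilcoxon_bonferroni",
]


@dataclass
class GroupedCounts:
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if np.any(self.values < 0):
            raise ValueError("observation counts must be >= 0")


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value; requires 3 <= n <= 5000 non-constant values."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant data")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list[GroupedCounts]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = #groups - 1)."""
    if len(groups) < 2 or any(g.values.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([g.values for g in groups])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical: H = 0", stacklevel=2)
        return 0.0, 1.0
    h, p = stats.kruskal(*[g.values for g in groups])
    return float(h), float(p)


def _rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration for small untied
    samples, normal approximation with continuity correction otherwise."""
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if max(a.size, b.size) <= 20 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True).pvalue
    )


def pairwise_wilcoxon_bonferroni(groups: list[GroupedCounts]) -> pd.DataFrame:
    """All pairwise rank-sum tests, Bonferroni-adjusted (x n_pairs, capped at 1).

    Pairs involving a group with fewer than two values are reported with a
    NaN p-value (untested).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        if gi.values.size < 2 or gj.values.size < 2:
            p_adj = np.nan
        else:
            p_adj = min(1.0, m * _rank_sum(gi.values.astype(float), gj.values.astype(float)))
        rows.append({"group_a": gi.group, "group_b": gj.group, "p_adjusted": p_adj})
    return pd.DataFrame(rows)
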