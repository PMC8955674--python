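"""Nonparametric group comparison: Mann-Whitney, Kruskal-Wallis, Bonferroni.

Pain scores are compared with the two-sided Mann-Whitney U test (exact null
distribution for small tie-free samples, tie-corrected normal approximation
otherwise); HRV metrics across >= 3 groups with the Kruskal-Wallis H test,
followed post hoc by pairwise Mann-Whitney tests under Bonferroni
correction.  Group summaries are mean +- SEM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .exceptions import ValidationError

#: Largest min(n) at which the exact Mann-Whitney null is used (tie-free data).
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    group_sizes: tuple
    adjusted_p: float | None = None


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float
    n: int


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when ``min(n) <= 8`` and the pooled
    data are tie-free, else the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(a.size, b.size) <= EXACT_MW_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="mann-whitney-exact" if exact else "mann-whitney-asymptotic",
        group_sizes=(int(a.size), int(b.size)),
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p with k-1 df).

    All-identical data across all groups yields H = 0, p = 1 rather than an
    error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size == 0 for g in arrays):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    sizes = tuple(int(g.size) for g in arrays)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, "kruskal-wallis", sizes)
    res = stats.kruskal(*arrays)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal-wallis", sizes)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Multiply each p by the number of comparisons, capped at 1."""
    p_values = list(p_values)
    m = len(p_values) if m is None else m
    return [min(1.0, p * m) for p in p_values]


def posthoc_pairwise(groups, labels=None) -> list[tuple]:
    """Pairwise Mann-Whitney tests with Bonferroni over the number of pairs.

    Returns a list of ((label_i, label_j), TestResult) where the result
    carries the adjusted p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    labels = list(range(len(arrays))) if labels is None else list(labels)
    pairs = list(combinations(range(len(arrays)), 2))
    raw = [mann_whitney(arrays[i], arrays[j]) for i, j in pairs]
    adjusted = bonferroni([r.p_value for r in raw])
    out = []
    for (i, j), r, adj in zip(pairs, raw, adjusted):
        out.append((
            (labels[i], labels[j]),
            TestResult(r.statistic, r.p_value, r.method, r.group_sizes, adjusted_p=adj),
        ))
    return out


def summarize(values) -> GroupSummary:
    """Mean +- SEM (sample SD / sqrt(n)); a single value gets SEM 0 with a warning."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot summarize an empty group")
    mean = float(np.mean(values))
    if values.size == 1:
        warnings.warn("SEM undefined for n = 1; reporting 0", stacklevel=2)
        return GroupSummary(mean=mean, sem=0.0, n=1)
    sem = float(np.std(values, ddof=1) / math.sqrt(values.size))
    return GroupSummary(mean=mean, sem=sem, n=int(values.size))
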