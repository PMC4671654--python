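"""Population-level copy-number tabulation and the two hypothesis tests used
to compare copy-number distributions: the Kruskal-Wallis rank-sum test
(across human populations) and the Welch two-sample t-test (between
species).  Both statistics are computed from their defining formulas; tail
probabilities come from the chi-square and t distributions, with an exact
permutation p-value available for small Kruskal-Wallis problems.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatResult", "cn_distribution", "kruskal_wallis", "welch_t"]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: float | tuple
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def cn_distribution(samples) -> pd.DataFrame:
    """Per-population frequency table of the diploid 45 kb LCR copy number.

    Rows are populations plus an aggregate 'all' row; columns are observed
    copy-number classes; each row sums to 1.
    """
    if not samples:
        raise ValueError("at least one sample required")
    rows = [(s.population, int(round(s.genotype.total45))) for s in samples]
    df = pd.DataFrame(rows, columns=["population", "cn"])
    table = pd.crosstab(df["population"], df["cn"])
    table.loc["all"] = table.sum(axis=0)
    freq = table.div(table.sum(axis=1), axis=0)
    freq.columns = [f"CN{c}" for c in freq.columns]
    return freq


def _h_statistic(values: np.ndarray, sizes) -> float:
    """Kruskal-Wallis H with tie correction, groups given by consecutive
    runs of ``sizes`` within ``values``."""
    n = len(values)
    ranks = sps.rankdata(values)  # average ranks for ties
    h = 0.0
    start = 0
    for sz in sizes:
        rbar = ranks[start : start + sz].mean()
        h += sz * (rbar - (n + 1) / 2.0) ** 2
        start += sz
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie <= 0.0:
        return 0.0  # every value tied
    return h / tie


def kruskal_wallis(groups, exact: bool = False, exact_max_n: int = 10) -> StatResult:
    """Kruskal-Wallis rank-sum test across two or more groups.

    The H statistic uses the standard tie correction; the p-value comes from
    the chi-square approximation with k-1 degrees of freedom, or from exact
    enumeration of all group assignments when ``exact`` and the total sample
    size is at most ``exact_max_n``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h = _h_statistic(pooled, sizes)
    df = len(groups) - 1
    if exact:
        n = len(pooled)
        if n > exact_max_n:
            raise ValueError(f"exact enumeration limited to n <= {exact_max_n}")
        ge = total = 0
        for perm in _group_assignments(n, sizes):
            total += 1
            if _h_statistic(pooled[perm], sizes) >= h - 1e-12:
                ge += 1
        return StatResult(float(h), float(df), ge / total,
                          "kruskal-wallis (exact permutation)")
    p = float(sps.chi2.sf(h, df)) if h > 0 else 1.0
    return StatResult(float(h), float(df), p, "kruskal-wallis (chi-square)")


def _group_assignments(n: int, sizes):
    """All partitions of indices 0..n-1 into ordered groups of given sizes."""
    def rec(remaining, sizes):
        if not sizes:
            yield []
            return
        k = sizes[0]
        for combo in itertools.combinations(remaining, k):
            rest = [x for x in remaining if x not in combo]
            for tail in rec(rest, sizes[1:]):
                yield list(combo) + tail
    for assignment in rec(list(range(n)), list(sizes)):
        yield np.array(assignment)


def welch_t(a, b) -> StatResult:
    """Welch two-sample t-test (unequal variances), two-sided.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("zero variance in both groups")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(float(t), float(df), p, "welch t-test")
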