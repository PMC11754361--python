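"""Nonparametric statistical layer.

Signal ratios and staining measurements from small surgical cohorts are not
normally distributed, so group comparisons use rank tests: Mann-Whitney for
two groups, Kruskal-Wallis for more, Dunn's z post hoc with multiplicity
adjustment, and Spearman rank correlation. Boxplot summaries follow the
min-max whisker convention (whiskers at the extremes, box at the quartiles,
no 1.5*IQR fences). Two-sided tests throughout; p < 0.05 is the
significance convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from fgsquant.exceptions import ConfigError, UndefinedStatisticError

ADJUSTMENTS = {"holm": "holm", "bonferroni": "bonferroni", "none": None}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str
    adjustment: str | None = None
    extra: dict | None = None


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q25: float
    q75: float
    minimum: float
    maximum: float
    n: int


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise UndefinedStatisticError("empty sample")
    return arr


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null distribution when the smaller group has n <= 8 and there are
    no ties; normal approximation with tie correction otherwise.
    """
    x, y = _clean(x), _clean(y)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        n_per_group=(len(x), len(y)), method=f"mann-whitney ({method})",
    )


def kruskal_wallis(groups, exact_max_n: int = 10) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square reference p.

    For tiny samples (total n <= ``exact_max_n``) an exact permutation p
    over all group assignments is computed alongside and reported in
    ``extra['p_permutation']``.
    """
    gs = [_clean(g) for g in groups]
    if len(gs) < 2:
        raise UndefinedStatisticError("need at least 2 groups")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        raise UndefinedStatisticError("all values identical: H is degenerate")
    h, p = scipy.stats.kruskal(*gs)
    extra = None
    total = sum(len(g) for g in gs)
    if total <= exact_max_n:
        extra = {"p_permutation": _kw_permutation_p(gs, float(h))}
    return TestResult(
        statistic=float(h), p_value=float(p),
        n_per_group=tuple(len(g) for g in gs),
        method="kruskal-wallis (chi-square)", extra=extra,
    )


def _kw_h(values: np.ndarray, sizes: list[int]) -> float:
    ranks = scipy.stats.rankdata(values)
    n = len(values)
    start, ssq = 0, 0.0
    for sz in sizes:
        r = ranks[start:start + sz].sum()
        ssq += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * ssq - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else math.nan


def _kw_permutation_p(gs: list[np.ndarray], h_obs: float) -> float:
    pooled = np.concatenate(gs)
    sizes = [len(g) for g in gs]
    n = len(pooled)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        h = _kw_h(pooled[list(perm)], sizes)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def dunn_posthoc(groups, adjustment: str = "holm") -> list[TestResult]:
    """Dunn's z post hoc on every pair of groups after Kruskal-Wallis.

    z uses the pooled-rank variance with tie correction; p-values are
    two-sided normal and adjusted for multiplicity across all pairs.
    """
    if adjustment not in ADJUSTMENTS:
        raise ConfigError(f"unknown adjustment {adjustment!r}; options: {sorted(ADJUSTMENTS)}")
    gs = [_clean(g) for g in groups]
    if len(gs) < 2:
        raise UndefinedStatisticError("need at least 2 groups")
    pooled = np.concatenate(gs)
    n = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in gs:
        sz = len(g)
        mean_ranks.append(ranks[start:start + sz].mean())
        sizes.append(sz)
        start += sz
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(gs)), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(z)
        ps.append(2.0 * scipy.stats.norm.sf(abs(z)))
    if ADJUSTMENTS[adjustment] is None:
        adj = ps
    else:
        adj = multipletests(ps, method=ADJUSTMENTS[adjustment])[1]
    return [
        TestResult(
            statistic=float(z), p_value=float(min(p, 1.0)),
            n_per_group=(sizes[i], sizes[j]), method="dunn",
            adjustment=adjustment,
            extra={"pair": (i, j), "p_unadjusted": float(pu)},
        )
        for (i, j), z, pu, p in zip(pairs, zs, ps, adj)
    ]


def spearman(x, y, exact_max_n: int = 7) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    p is exact by permutation enumeration for n <= ``exact_max_n``,
    otherwise the t approximation.
    """
    x, y = _clean(x), _clean(y)
    if len(x) != len(y):
        raise UndefinedStatisticError("spearman needs paired samples")
    if len(x) < 3:
        raise UndefinedStatisticError("spearman needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for a constant sample")
    rho, p_t = scipy.stats.spearmanr(x, y)
    method = "spearman (t approximation)"
    p = float(p_t)
    if len(x) <= exact_max_n:
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            total += 1
            if r >= obs - 1e-12:
                count += 1
        p = count / total
        method = "spearman (exact permutation)"
    return TestResult(statistic=float(rho), p_value=min(p, 1.0),
                      n_per_group=(len(x),), method=method)


def boxplot_summary(values) -> BoxplotSummary:
    """Min-max-whisker boxplot summary; quartiles by linear interpolation."""
    arr = _clean(values)
    q25, med, q75 = np.percentile(arr, [25, 50, 75])  # type-7 linear interpolation
    return BoxplotSummary(
        median=float(med), q25=float(q25), q75=float(q75),
        minimum=float(arr.min()), maximum=float(arr.max()), n=len(arr),
    )


def kw_power_simulation(group_means, sd: float, n_per_group: int, seed: int,
                        n_sims: int = 500, alpha: float = 0.05) -> float:
    """Monte-Carlo power of Kruskal-Wallis for a given location-shift design.

    Draws normal groups at the stated means / common SD and returns the
    fraction of simulations with p < alpha.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        gs = [rng.normal(m, sd, size=n_per_group) for m in group_means]
        if scipy.stats.kruskal(*gs)[1] < alpha:
            hits += 1
    return hits / n_sims
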