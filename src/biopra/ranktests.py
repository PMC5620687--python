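"""Tie-corrected rank tests for comparing forecast and observed distributions.

Monte Carlo forecasts are compared with the nonparametric tests the study
relied on: the Mann–Whitney rank-sum test for two groups and the
Kruskal–Wallis ANOVA on ranks for several.  Both are implemented here from
mid-ranks with the standard tie corrections, so the arithmetic is fully
auditable; `scipy.stats` serves as an independent cross-check in the test
suite, not as the implementation.

For small problems (pooled N <= 12) both tests switch to the exact permutation
null — every assignment of the pooled observations to groups is enumerated —
so the asymptotic approximations can be verified against ground truth.

Reported pieces:

* ``rank_sum_T`` — the rank sum of the smaller group (first group on a size
  tie).  Statistics packages often print this as "T"; for 2000-trial
  forecasts it reaches the millions, which is why published rank-sum values
  of that magnitude are rank sums, not t statistics.
* ``statistic_U`` — ``T - n(n+1)/2`` for the same group, in [0, n1*n2].
* ``z`` — normal deviate of U using the tie-corrected variance, by default
  without continuity correction (the forecasts compared are large; the
  correction is switchable).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["TestResult", "rank_with_ties", "mann_whitney", "kruskal_wallis", "EXACT_LIMIT"]

#: Largest pooled size for which the exact permutation null is enumerated.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test; unused fields are None."""

    test: str
    p_two_sided: float
    statistic_U: Optional[float] = None
    rank_sum_T: Optional[float] = None
    statistic_H: Optional[float] = None
    z: Optional[float] = None
    df: int = 0
    method: str = "normal_approximation"
    group_sizes: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        return d


def rank_with_ties(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks of a vector: tied values share the mean of the ranks they span."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("values must be a non-empty 1-d sequence")
    return stats.rankdata(arr, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _u_from_ranks(ranks: np.ndarray, idx: Sequence[int], n: int) -> float:
    t = float(np.sum(ranks[list(idx)]))
    return t - n * (n + 1) / 2.0


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    *,
    continuity_correction: bool = False,
    exact: Optional[bool] = None,
) -> TestResult:
    """Two-sample Mann–Whitney rank-sum test with tie correction.

    Parameters
    ----------
    x, y
        The two groups (non-empty).
    continuity_correction
        Apply the 0.5 continuity correction to the normal deviate.  Off by
        default: the comparisons this package makes are between Monte Carlo
        forecasts of thousands of trials.
    exact
        Force (True) or forbid (False) the exact permutation p-value.  By
        default it is used automatically when ``len(x) + len(y) <= EXACT_LIMIT``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(xa), len(ya)
    pooled = np.concatenate([xa, ya])
    big_n = n1 + n2
    ranks = rank_with_ties(pooled)

    # report the smaller group (first group on a size tie)
    if n1 <= n2:
        rep_idx, n_rep, n_other = range(n1), n1, n2
    else:
        rep_idx, n_rep, n_other = range(n1, big_n), n2, n1
    rank_sum_t = float(np.sum(ranks[list(rep_idx)]))
    u = rank_sum_t - n_rep * (n_rep + 1) / 2.0

    mu = n_rep * n_other / 2.0
    tie = _tie_term(pooled)
    var = n_rep * n_other / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
    if var <= 0:
        z = 0.0
    else:
        dev = u - mu
        if continuity_correction and dev != 0:
            dev -= math.copysign(0.5, dev)
        z = dev / math.sqrt(var)
    p_normal = min(1.0, 2.0 * stats.norm.sf(abs(z)))

    use_exact = exact if exact is not None else big_n <= EXACT_LIMIT
    if use_exact:
        if math.comb(big_n, n_rep) > 200_000:
            raise ValueError("exact permutation infeasible at this sample size")
        dev_obs = abs(u - mu)
        hits = total = 0
        for combo in itertools.combinations(range(big_n), n_rep):
            total += 1
            if abs(_u_from_ranks(ranks, combo, n_rep) - mu) >= dev_obs - 1e-12:
                hits += 1
        return TestResult(
            test="mann_whitney",
            p_two_sided=hits / total,
            statistic_U=u,
            rank_sum_T=rank_sum_t,
            z=z,
            method="exact_permutation",
            group_sizes=(n1, n2),
        )
    return TestResult(
        test="mann_whitney",
        p_two_sided=p_normal,
        statistic_U=u,
        rank_sum_T=rank_sum_t,
        z=z,
        method="normal_approximation",
        group_sizes=(n1, n2),
    )


def _h_statistic(pooled_ranks: np.ndarray, sizes: Sequence[int], tie: float) -> float:
    big_n = len(pooled_ranks)
    h = 0.0
    start = 0
    for n_j in sizes:
        r_j = float(np.sum(pooled_ranks[start : start + n_j]))
        h += r_j * r_j / n_j
        start += n_j
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    correction = 1.0 - tie / (big_n**3 - big_n)
    if correction <= 0:  # every pooled value identical
        return 0.0
    return h / correction


def kruskal_wallis(groups: Sequence[Sequence[float]], *, exact: Optional[bool] = None) -> TestResult:
    """Kruskal–Wallis ANOVA on ranks with tie correction.

    H is referred to the chi-square distribution with k-1 degrees of freedom,
    or to the exact permutation null for pooled N <= EXACT_LIMIT (or when
    ``exact=True``).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    sizes = [len(a) for a in arrays]
    pooled = np.concatenate(arrays)
    big_n = len(pooled)
    ranks = rank_with_ties(pooled)
    tie = _tie_term(pooled)
    h = _h_statistic(ranks, sizes, tie)
    df = len(arrays) - 1
    p_chi2 = float(stats.chi2.sf(h, df))

    use_exact = exact if exact is not None else big_n <= EXACT_LIMIT
    if use_exact:
        n_arr = math.factorial(big_n)
        for n_j in sizes:
            n_arr //= math.factorial(n_j)
        if n_arr > 500_000:
            raise ValueError("exact permutation infeasible at these group sizes")
        hits = total = 0
        for perm in _group_assignments(big_n, sizes):
            total += 1
            if _h_statistic(ranks[perm], sizes, tie) >= h - 1e-12:
                hits += 1
        return TestResult(
            test="kruskal_wallis",
            p_two_sided=hits / total,
            statistic_H=h,
            df=df,
            method="exact_permutation",
            group_sizes=tuple(sizes),
        )
    return TestResult(
        test="kruskal_wallis",
        p_two_sided=p_chi2,
        statistic_H=h,
        df=df,
        method="chi_square",
        group_sizes=tuple(sizes),
    )


def _group_assignments(big_n: int, sizes: Sequence[int]):
    """Yield index permutations realizing every distinct split into the groups."""

    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield combo + tail

    for assignment in rec(tuple(range(big_n)), list(sizes)):
        yield np.asarray(assignment, dtype=int)
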