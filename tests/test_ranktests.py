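"""Rank tests: mid-ranks, tie corrections, exact permutation nulls, scipy cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from biopra import kruskal_wallis, mann_whitney, rank_with_ties


class TestRankWithTies:
    def test_distinct_values(self):
        np.testing.assert_array_equal(rank_with_ties([3, 1, 2]), [3, 1, 2])

    def test_full_tie_shares_midrank(self):
        np.testing.assert_array_equal(rank_with_ties([5, 5]), [1.5, 1.5])

    def test_partial_tie(self):
        np.testing.assert_array_equal(rank_with_ties([1, 2, 2, 3]), [1, 2.5, 2.5, 4])

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_ranks_sum_to_triangular_number(self, values):
        n = len(values)
        assert np.sum(rank_with_ties(values)) == pytest.approx(n * (n + 1) / 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_with_ties([])


class TestMannWhitney:
    def test_identical_groups_give_null_result(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z == 0.0
        assert res.p_two_sided == 1.0

    def test_complete_separation_exact_p(self):
        # all 20 assignments of 6 values to two groups of 3; only the two
        # extreme splits are as extreme as the observed U=0
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic_U == 0.0
        assert res.method == "exact_permutation"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_rank_sum_reported_for_smaller_group(self):
        res = mann_whitney([10.0, 20.0], [1.0, 2.0, 3.0])
        # smaller group occupies the top two ranks: T = 4 + 5
        assert res.rank_sum_T == pytest.approx(9.0)
        assert res.statistic_U <= 2 * 3

    def test_exact_equals_brute_force_with_ties(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        res = mann_whitney(x, y)
        assert res.method == "exact_permutation"
        # brute force over all 20 index splits of the pooled mid-ranks
        from itertools import combinations

        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        mu = 3 * 3 / 2.0
        u_obs = abs(np.sum(ranks[:3]) - 6.0 - mu)
        hits = sum(
            1
            for c in combinations(range(6), 3)
            if abs(np.sum(ranks[list(c)]) - 6.0 - mu) >= u_obs - 1e-12
        )
        assert res.p_two_sided == pytest.approx(hits / 20)

    def test_matches_scipy_on_large_tied_samples(self, rng):
        x = np.round(rng.beta(2, 5, size=300), 2)  # rounding induces many ties
        y = np.round(rng.beta(2, 4, size=250), 2)
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(0.5, size=35)
        a = mann_whitney(x, y, exact=False)
        b = mann_whitney(np.exp(x), np.exp(y), exact=False)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)
        assert a.statistic_U == b.statistic_U

    def test_type_one_error_near_nominal(self, rng):
        # null rejection rate at alpha=0.05, n1=n2=50
        rejections = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            if mann_whitney(x, y, exact=False).p_two_sided < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_give_h_zero(self):
        res = kruskal_wallis([[1, 2], [1, 2], [1, 2]], exact=False)
        assert res.statistic_H == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_exact_permutation_for_three_small_groups(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.method == "exact_permutation"
        # complete separation: the observed ordering is among the most extreme
        ref = sps.kruskal([1, 2], [3, 4], [5, 6])
        assert res.statistic_H == pytest.approx(ref.statistic)
        # brute force: 90 distinct splits; all with H >= observed counted
        assert 0 < res.p_two_sided < 0.2

    def test_matches_scipy_with_ties(self, rng):
        groups = [np.round(rng.beta(2, 5, size=80), 2) for _ in range(3)]
        ours = kruskal_wallis(groups, exact=False)
        ref = sps.kruskal(*groups)
        assert ours.statistic_H == pytest.approx(ref.statistic, rel=1e-9)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)
        assert ours.df == 2

    def test_two_group_h_equals_z_squared_without_ties(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(0.3, size=50)
        mw = mann_whitney(x, y, exact=False)
        kw = kruskal_wallis([x, y], exact=False)
        assert kw.statistic_H == pytest.approx(mw.z**2, rel=1e-9)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestExactOracleEquality:
    """The fast exact paths must equal naive enumeration for every small input."""

    @given(
        x=st.lists(st.integers(0, 4), min_size=1, max_size=5),
        y=st.lists(st.integers(0, 4), min_size=1, max_size=5),
    )
    @settings(max_examples=60, deadline=None)
    def test_mann_whitney_exact_matches_enumeration(self, x, y):
        from itertools import combinations

        res = mann_whitney(x, y)
        assert res.method == "exact_permutation"
        pooled = np.array(x + y, dtype=float)
        ranks = sps.rankdata(pooled)
        n1, n2 = len(x), len(y)
        n_rep = min(n1, n2)
        n_other = max(n1, n2)
        mu = n_rep * n_other / 2.0
        idx = range(n1) if n1 <= n2 else range(n1, n1 + n2)
        u_obs = abs(np.sum(ranks[list(idx)]) - n_rep * (n_rep + 1) / 2 - mu)
        total = hits = 0
        for c in combinations(range(n1 + n2), n_rep):
            total += 1
            u = np.sum(ranks[list(c)]) - n_rep * (n_rep + 1) / 2
            if abs(u - mu) >= u_obs - 1e-12:
                hits += 1
        assert res.p_two_sided == pytest.approx(hits / total)

    @given(
        data=st.lists(st.integers(0, 3), min_size=6, max_size=7),
    )
    @settings(max_examples=20, deadline=None)
    def test_kruskal_exact_matches_enumeration(self, data):
        # split the pooled data into three groups of fixed sizes
        n = len(data)
        groups = [data[:2], data[2:4], data[4:]]
        res = kruskal_wallis(groups)
        assert res.method == "exact_permutation"
        # independent enumeration via multiset permutations of group labels
        from itertools import permutations

        ranks = sps.rankdata(np.asarray(data, dtype=float))
        labels = [0] * 2 + [1] * 2 + [2] * (n - 4)

        def h_of(assign):
            sums = np.zeros(3)
            counts = np.zeros(3)
            for lab, r in zip(assign, ranks):
                sums[lab] += r
                counts[lab] += 1
            h = 12.0 / (n * (n + 1)) * np.sum(sums**2 / counts) - 3 * (n + 1)
            _, cnt = np.unique(ranks, return_counts=True)
            corr = 1.0 - np.sum(cnt.astype(float) ** 3 - cnt) / (n**3 - n)
            return h / corr if corr > 0 else 0.0

        h_obs = h_of(labels)
        seen = set()
        hits = total = 0
        for perm in permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if h_of(perm) >= h_obs - 1e-12:
                hits += 1
        assert res.statistic_H == pytest.approx(h_obs, abs=1e-9)
        assert res.p_two_sided == pytest.approx(hits / total)
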