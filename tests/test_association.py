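"""Rank correlation, top contributors, and overlap/enrichment tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import resilax as rx
from resilax.association import hypergeometric_enrichment, overlap_test, spearman

from conftest import make_axis


def brute_force_spearman_p(x, y):
    """Two-sided permutation p by full enumeration (test-side oracle)."""
    rx_ = stats.rankdata(x)
    obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        rho = stats.spearmanr(rx_, stats.rankdata(perm)).statistic
        count += abs(rho) >= obs - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 2, 3], [2, 4, 6]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [6, 4, 2]).rho == pytest.approx(-1.0)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [3, 4])

    def test_missing_pairs_dropped(self):
        res = spearman([1, 2, 3, np.nan, 5], [2, 4, 6, 8, np.nan])
        assert res.n == 3
        assert res.rho == pytest.approx(1.0)

    def test_exact_permutation_p_at_n4(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        res = spearman(x, y)
        assert res.rho == pytest.approx(0.8)
        assert res.p == pytest.approx(brute_force_spearman_p(x, y))
        # 8 of the 24 pairings reach |rho| >= 0.8
        assert res.p == pytest.approx(1 / 3)

    def test_exact_permutation_p_at_n5_with_ties(self):
        x, y = [1, 2, 2, 3, 4], [5, 3, 4, 2, 2]
        res = spearman(x, y)
        assert res.p == pytest.approx(brute_force_spearman_p(x, y))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        res = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-100, max_value=100), min_size=3,
                    max_size=20, unique=True))
    def test_self_correlation_is_one(self, x):
        assert spearman(x, x).rho == pytest.approx(1.0)


class TestTopContributors:
    def test_top_fraction_count(self):
        rng = np.random.default_rng(1)
        axis = make_axis(rng.normal(size=100))
        assert len(rx.top_contributors(axis, 0.05)) == 5

    def test_selection_and_direction_labels(self):
        axis = make_axis([0.9, -0.8, 0.1, 0.05, 0.02])
        top = rx.top_contributors(axis, 0.4)
        assert list(top["gene_id"]) == ["g0", "g1"]
        assert list(top["direction"]) == ["up", "down"]

    def test_ties_break_by_gene_id(self):
        axis = make_axis([0.5, -0.5, 0.5, 0.1])
        top = rx.top_contributors(axis, 0.5)
        assert list(top["gene_id"]) == ["g0", "g1"]

    def test_positive_shifted_loadings_give_more_up_labels(self):
        # mirrors the asymmetric loading distribution of a stress axis whose
        # strongest contributors are mostly upregulated genes
        rng = np.random.default_rng(2)
        axis = make_axis(rng.normal(0.1, 0.5, size=2000))
        top = rx.top_contributors(axis, 0.05)
        counts = top["direction"].value_counts()
        assert counts.get("up", 0) > counts.get("down", 0)

    def test_fraction_bounds(self):
        axis = make_axis([1.0, 0.5])
        with pytest.raises(ValueError):
            rx.top_contributors(axis, 0.0)


class TestHypergeometric:
    def test_complete_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        sets = rx.GeneSetCollection({"s": set(universe[:5])})
        rows = hypergeometric_enrichment(universe[:5], sets, universe)
        assert rows[0].p == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_has_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = rx.GeneSetCollection({"s": set(universe[:5])})
        rows = hypergeometric_enrichment(universe[10:15], sets, universe)
        assert rows[0].overlap == 0
        assert rows[0].p == pytest.approx(1.0)

    def test_small_set_fails_filter_regardless_of_p(self):
        universe = [f"g{i}" for i in range(20)]
        sets = rx.GeneSetCollection({"s": set(universe[:3])})
        rows = hypergeometric_enrichment(universe[:3], sets, universe)
        assert rows[0].p_bonferroni < 0.05
        assert not rows[0].passes_filter

    def test_query_outside_universe_rejected(self):
        sets = rx.GeneSetCollection({"s": {"g1"}})
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment(["zz"], sets, ["g1", "g2"])

    def test_tail_probability_matches_enumeration_for_small_universes(self):
        # every (N, K, n, k) with N <= 25 against the explicit tail sum
        from resilax.association import _hypergeom_upper_tail
        for N in range(1, 26):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 4):
                    for k in range(0, min(K, n) + 1):
                        expected = sum(
                            math.comb(K, j) * math.comb(N - K, n - j)
                            for j in range(k, min(K, n) + 1)
                        ) / math.comb(N, n)
                        assert _hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                            expected, rel=1e-10, abs=1e-12)


class TestOverlapTest:
    def test_forced_overlap_has_p_one_and_fails(self):
        genes = [f"g{i}" for i in range(30)]
        row = overlap_test(genes, genes, genes)
        assert row.p == pytest.approx(1.0)
        assert not row.passes_filter

    def test_overlap_of_exactly_ten_fails_the_strict_filter(self):
        universe = [f"g{i}" for i in range(1000)]
        query = universe[:10]
        reference = universe[:10] + universe[500:]
        row = overlap_test(query, reference, universe)
        assert row.overlap == 10
        assert not row.passes_filter

    def test_null_simulation_rarely_passes(self):
        rng = np.random.default_rng(3)
        universe = np.array([f"g{i}" for i in range(1000)])
        passes = 0
        for _ in range(1000):
            q = rng.choice(universe, 50, replace=False)
            ref = rng.choice(universe, 50, replace=False)
            passes += overlap_test(q, ref, universe).passes_filter
        assert passes / 1000 < 0.005
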