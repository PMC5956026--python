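"""Group statistics: Mann-Whitney (exact + asymptotic), Shapiro-Wilk,
per-category GF-vs-GC comparison."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bakescore import (Category, GlutenGroup, ScoringConfig, compare_groups,
                       mann_whitney, score_batch, shapiro_wilk)
from bakescore.stats import EXACT_ENUMERATION, NORMAL_APPROX, NOT_COMPARABLE

from conftest import make_product


def u_statistic(a, b):
    """Brute-force U for sample a: pairwise wins + half-ties."""
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


def exact_two_sided_p(a, b):
    """Independent oracle: full enumeration of group assignments.

    Two-sided p as twice the smaller tail probability of the exact U null
    distribution, capped at 1.
    """
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = u_statistic(a, b)
    us = [u_statistic([pooled[i] for i in idx],
                      [pooled[i] for i in range(len(pooled))
                       if i not in set(idx)])
          for idx in itertools.combinations(range(len(pooled)), n_a)]
    total = len(us)
    lo = sum(u <= u_obs for u in us) / total
    hi = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_separated_2v2_exact_p_is_one_third(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.U == 0
        assert r.method == EXACT_ENUMERATION
        assert r.p_value == pytest.approx(1 / 3)

    def test_identical_samples_give_central_u_and_p_one(self):
        a = [1.0, 2.5, 3.5, 7.0]
        r = mann_whitney(a, a)
        assert r.U == pytest.approx(len(a) ** 2 / 2)
        assert r.p_value == pytest.approx(1.0)

    @given(a=st.lists(st.integers(0, 13), min_size=2, max_size=15),
           b=st.lists(st.integers(0, 13), min_size=2, max_size=15))
    def test_rank_sum_identity_and_symmetry(self, a, b):
        ra = mann_whitney(a, b)
        rb = mann_whitney(b, a)
        assert ra.U + rb.U == pytest.approx(len(a) * len(b))
        assert ra.p_value == pytest.approx(rb.p_value)
        assert 0 < ra.p_value <= 1
        assert 0 <= ra.U <= len(a) * len(b)

    def test_exact_matches_enumeration_oracle_for_all_small_splits(self):
        """For every untied configuration with n1 + n2 <= 10, the exact
        p equals independent full enumeration of rank assignments."""
        rng = np.random.default_rng(42)
        for n1, n2 in [(1, 3), (2, 2), (2, 4), (3, 3), (3, 5), (4, 4),
                       (4, 6), (5, 5)]:
            n = n1 + n2
            for idx in itertools.combinations(range(n), n1):
                values = list(range(1, n + 1))
                a = [values[i] for i in idx]
                b = [values[i] for i in range(n) if i not in set(idx)]
                r = mann_whitney(a, b)
                assert r.method == EXACT_ENUMERATION
                assert r.p_value == pytest.approx(exact_two_sided_p(a, b)), \
                    (a, b)

    def test_exact_and_asymptotic_agree_for_untied_8_plus_8(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pooled = rng.permutation(np.arange(16.0) + rng.normal(0, 1e-6,
                                                                  16))
            a, b = pooled[:8], pooled[8:]
            exact = mann_whitney(a, b, exact_threshold=16)
            approx = mann_whitney(a, b, exact_threshold=0)
            assert approx.method == NORMAL_APPROX
            assert abs(exact.p_value - approx.p_value) < 0.03

    def test_ties_fall_back_to_corrected_normal_approximation(self):
        r = mann_whitney([1, 2, 2], [2, 3, 4])
        assert r.method == NORMAL_APPROX

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestShapiroWilk:
    def test_matches_external_reference_values(self):
        # reference values computed independently with R's shapiro.test
        w, p = shapiro_wilk([148, 154, 158, 160, 161, 162, 166, 170, 182,
                             195, 236])
        assert w == pytest.approx(0.7888, abs=5e-4)
        assert p == pytest.approx(0.0067, abs=5e-4)
        w2, p2 = shapiro_wilk([2.1, 3.4, 1.9, 2.8, 3.0, 2.2, 2.5, 3.1, 2.7,
                               2.9, 2.3, 2.6])
        assert w2 == pytest.approx(0.9867, abs=5e-4)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_affine_invariance_of_w(self, scale, shift):
        x = np.array([1.2, 5.0, 2.2, 8.8, 3.1, 4.0, 2.9, 7.3])
        w0, _ = shapiro_wilk(x)
        w1, _ = shapiro_wilk(scale * x + shift)
        assert w1 == pytest.approx(w0, rel=1e-6)

    def test_discrete_scores_rejected_as_normal_at_large_n(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 4, size=200).astype(float)
        _, p = shapiro_wilk(scores)
        assert p < 0.05

    @pytest.mark.parametrize("bad", [[1.0, 2.0], [3.0] * 10])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            shapiro_wilk(bad)


def two_group_results(gf_scores, gc_scores, category=Category.BREAD):
    products = []
    for i, s in enumerate(gf_scores):
        products.append(make_product(
            pid=f"gf{i}", category=category, group=GlutenGroup.GF,
            ingredients=_ingredients_for_score(s)))
    for i, s in enumerate(gc_scores):
        products.append(make_product(
            pid=f"gc{i}", category=category, group=GlutenGroup.GC,
            ingredients=_ingredients_for_score(s)))
    return score_batch(products).results


def _ingredients_for_score(target):
    """Ingredient lists realising bread qualitative subtotals 0..6."""
    favourable = ["wholegrain flour", "sourdough", "chickpea flour",
                  "buckwheat flour"]
    items = []
    first = "rice flour" if target >= 1 else "potato starch"
    extra = max(0, min(target - 1, 4) if target >= 1 else 0)
    items = [first] + favourable[:extra]
    if target < 6:  # keep emulsifier unless aiming for the full 6
        items.append("mono and diglycerides of fatty acids")
    return tuple(items)


class TestCompareGroups:
    def test_complete_separation_is_significant(self):
        results = two_group_results([0, 1] * 10, [4, 5, 6] * 7)
        (comp,) = compare_groups(results)
        assert comp.category is Category.BREAD
        assert (comp.n_gf, comp.n_gc) == (20, 21)
        assert comp.significant and comp.p_value < 0.001

    def test_quantitative_only_uses_quant_subtotals(self):
        # identical qualitative profiles, different nutrition facts
        products = (
            [make_product(pid=f"gf{i}", group=GlutenGroup.GF,
                          total_fat=10.0) for i in range(12)]
            + [make_product(pid=f"gc{i}", group=GlutenGroup.GC,
                            total_fat=2.0, saturated_fat=1.0,
                            sodium=0.1, sugars=1.0, fiber=5.0)
               for i in range(12)])
        results = score_batch(products).results
        (full,) = compare_groups(results)
        (quant,) = compare_groups(results, quantitative_only=True)
        assert quant.significant
        assert quant.U == full.U  # qual profiles identical -> same ranks

    def test_single_group_category_reported_not_comparable(self):
        results = score_batch(
            [make_product(pid="a", category=Category.COOKIES,
                          group=GlutenGroup.GF)]).results
        (comp,) = compare_groups(results)
        assert comp.method == NOT_COMPARABLE
        assert comp.p_value is None and not comp.significant
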