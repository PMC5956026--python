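"""Ingredient rules: lexicon detection, polarity, category applicability."""

import pytest
from hypothesis import given, strategies as st

from bakescore import (Category, Polarity, default_qualitative_rules,
                       detect, normalize, score_qualitative)

from conftest import EXEMPLAR, make_product


def rules_by_name():
    return {r.name: r for r in default_qualitative_rules()}


class TestDefaultRules:
    def test_seven_rules_with_expected_polarities(self):
        rules = rules_by_name()
        assert len(rules) == 7
        zero_on_presence = {"starch_first", "fructose", "emulsifiers"}
        for name, rule in rules.items():
            expected = (Polarity.PRESENCE_SCORES_ZERO
                        if name in zero_on_presence
                        else Polarity.PRESENCE_SCORES_ONE)
            assert rule.polarity is expected

    def test_applicability_matrix(self):
        rules = rules_by_name()
        assert rules["fructose"].applicable_categories == \
            {Category.COOKIES, Category.BREAKFAST_PASTRIES}
        assert rules["sourdough"].applicable_categories == {Category.BREAD}
        per_category = {
            Category.BREAD: 6, Category.BREAD_SUBSTITUTES: 5,
            Category.BREAKFAST_PASTRIES: 5, Category.COOKIES: 4}
        for category, expected in per_category.items():
            assert sum(r.applies_to(category)
                       for r in rules.values()) == expected

    def test_unknown_rule_override_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            default_qualitative_rules(lexicons={"palm_oil": ["palm oil"]})


class TestDetect:
    @pytest.mark.parametrize("rule,ingredient", [
        ("emulsifiers", "mono- and diglycerides of fatty acids"),
        ("emulsifiers", "emulsifier: E471"),
        ("wholegrain_flours", "farina integrale di riso"),
        ("wholegrain_flours", "WHOLEMEAL flour"),
        ("sourdough", "lievito madre"),
        ("other_flours", "grano saraceno"),
        ("fructose", "high fructose corn syrup"),
        ("legume_flours", "farina di ceci"),
    ])
    def test_lexicon_hits(self, rule, ingredient):
        assert detect(rules_by_name()[rule], ["water", ingredient])

    @pytest.mark.parametrize("rule,ingredient", [
        ("other_flours", "corn starch"),      # corn excluded by definition
        ("other_flours", "farina di riso"),   # rice excluded
        ("legume_flours", "peanut oil"),      # not a legume flour context
        ("sourdough", "yeast"),
        ("emulsifiers", "sunflower lecithin"),
    ])
    def test_non_hits(self, rule, ingredient):
        assert not detect(rules_by_name()[rule], ["water", ingredient])

    def test_starch_first_is_positional(self):
        starch = rules_by_name()["starch_first"]
        assert detect(starch, ["potato starch", "rice flour"])
        assert not detect(starch, ["rice flour", "potato starch"])

    def test_empty_ingredient_list_is_an_error(self):
        with pytest.raises(ValueError):
            detect(rules_by_name()["sourdough"], [])

    @given(term=st.sampled_from(sorted(EXEMPLAR.values())),
           spaces=st.integers(1, 3),
           upper=st.booleans())
    def test_detection_invariant_to_case_and_whitespace(self, term, spaces,
                                                        upper):
        mangled = (" " * spaces) + (term.upper() if upper else term) + "  "
        mangled = mangled.replace(" ", " " * spaces)
        hits = {r.name for r in default_qualitative_rules()
                if detect(r, [mangled])
                or (r.positional and detect(r, [mangled]))}
        clean_hits = {r.name for r in default_qualitative_rules()
                      if detect(r, [term])}
        assert hits == clean_hits

    def test_accent_folding(self):
        assert normalize("Lìevito Màdre") == "lievito madre"
        assert detect(rules_by_name()["sourdough"], ["lìevito màdre"])


class TestScoreQualitative:
    def test_all_absent_bread_scores_absence_polarities(self):
        # nothing flagged at all: the three presence-scores-zero rules that
        # apply to bread are starch_first and emulsifiers -> 2 points
        score = score_qualitative(make_product(ingredients=("water",)))
        assert score.subtotal == 2
        assert score.points == {"starch_first": 1, "wholegrain_flours": 0,
                                "sourdough": 0, "legume_flours": 0,
                                "other_flours": 0, "emulsifiers": 1}

    def test_fully_favourable_bread_scores_six(self):
        ingredients = ("rice flour", EXEMPLAR["wholegrain_flours"],
                       EXEMPLAR["sourdough"], EXEMPLAR["legume_flours"],
                       EXEMPLAR["other_flours"], "water")
        score = score_qualitative(make_product(ingredients=ingredients))
        assert score.subtotal == 6

    def test_fully_unfavourable_cookie_scores_zero(self):
        ingredients = (EXEMPLAR["starch_first"], "corn syrup", "E471",
                       "sugar")
        score = score_qualitative(
            make_product(category=Category.COOKIES,
                         ingredients=ingredients))
        assert score.subtotal == 0

    def test_non_applicable_rules_are_omitted_not_zero(self):
        score = score_qualitative(
            make_product(category=Category.COOKIES, ingredients=("water",)))
        assert set(score.points) == {"starch_first", "other_flours",
                                     "fructose", "emulsifiers"}
        assert "sourdough" not in score.presence

    @given(extra=st.sampled_from(["wholegrain_flours", "sourdough",
                                  "legume_flours", "other_flours"]),
           base=st.lists(st.sampled_from(["water", "sea salt", "corn syrup",
                                          "E471", "rice flour"]),
                         min_size=1, max_size=4))
    def test_adding_favourable_ingredient_never_decreases_subtotal(
            self, extra, base):
        before = score_qualitative(make_product(ingredients=tuple(base)))
        after = score_qualitative(
            make_product(ingredients=tuple(base) + (EXEMPLAR[extra],)))
        assert after.subtotal >= before.subtotal

    def test_ceiling_equals_applicable_rule_count(self):
        for category in Category:
            rules = [r for r in default_qualitative_rules()
                     if r.applies_to(category)]
            favourable = [EXEMPLAR[r.name] for r in rules
                          if r.polarity is Polarity.PRESENCE_SCORES_ONE]
            product = make_product(category=category,
                                   ingredients=("rice flour",
                                                *favourable, "water"))
            assert score_qualitative(product).subtotal == len(rules)
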