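import hypothesis
import pytest

from bakescore import Category, GlutenGroup, NutritionFacts, Product

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[hypothesis.HealthCheck.too_slow])
hypothesis.settings.load_profile("ci")


#: Facts attaining the most favourable tier of every quantitative rule.
BEST_FACTS = dict(total_fat=2.9, saturated_fat=1.0, sodium=0.10,
                  fiber=4.0, sugars=0.01)
#: Facts failing every tier.
WORST_FACTS = dict(total_fat=10.0, saturated_fat=5.0, sodium=1.0,
                   fiber=1.0, sugars=20.0)

#: One ingredient exemplar per rule, triggering exactly that rule.
EXEMPLAR = {
    "starch_first": "potato starch",
    "wholegrain_flours": "wholegrain flour",
    "sourdough": "sourdough",
    "legume_flours": "chickpea flour",
    "other_flours": "buckwheat flour",
    "fructose": "glucose fructose syrup",
    "emulsifiers": "mono and diglycerides of fatty acids",
}


def make_product(category=Category.BREAD, group=GlutenGroup.GF,
                 ingredients=("rice flour", "water"), pid="p1",
                 **facts) -> Product:
    merged = {**WORST_FACTS, **facts}
    return Product(id=pid, category=category, group=group,
                   facts=NutritionFacts(**merged),
                   ingredients=tuple(ingredients))


@pytest.fixture
def best_facts() -> NutritionFacts:
    return NutritionFacts(**BEST_FACTS)


@pytest.fixture
def worst_facts() -> NutritionFacts:
    return NutritionFacts(**WORST_FACTS)
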