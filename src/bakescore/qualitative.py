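"""Qualitative sub-score: presence/absence of seven formulation ingredients.

Seven nutritionally relevant formulation features are detected in the
on-pack ingredient list and converted into 0/1 points per rule:

==================  ========================  =============================
rule                point earned when ...     applicable categories
==================  ========================  =============================
starch_first        starch NOT first          all four
wholegrain_flours   present                   bread, substitutes, pastries
sourdough           present                   bread only
legume_flours       present                   bread, substitutes
other_flours        present                   all four
fructose            absent                    cookies, pastries
emulsifiers         absent                    all four
==================  ========================  =============================

"Other flours" means flours from minor cereals / pseudocereals used as an
alternative to wheat or to the traditional gluten-free cereals — buckwheat,
quinoa, amaranth, sorghum, millet, teff, and the non-wheat gluten cereals rye
and barley; rice and corn are explicitly excluded.  ``starch_first`` is
positional: it fires only when the first (heaviest) ingredient is a starch.
Detection is substring matching of a bilingual (English + Italian) lexicon on
normalised text: lower-cased, accent-folded, hyphens treated as spaces,
whitespace collapsed.

The applicability matrix determines each category's score ceiling
(7 + number of applicable rules): bread 13, bread substitutes 12, breakfast
pastries 12, cookies 11.  Both the lexicons and the matrix are data and can
be overridden from a YAML config.
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .products import Category, Product

RULE_NAMES = (
    "starch_first",
    "wholegrain_flours",
    "sourdough",
    "legume_flours",
    "other_flours",
    "fructose",
    "emulsifiers",
)


class Polarity(str, Enum):
    #: presence of the ingredient earns zero points (absence earns the point)
    PRESENCE_SCORES_ZERO = "presence_scores_zero"
    #: presence of the ingredient earns the point
    PRESENCE_SCORES_ONE = "presence_scores_one"


@lru_cache(maxsize=65536)
def normalize(text: str) -> str:
    """Normalise label text for matching.

    Lower-case, strip accents (NFKD fold), replace hyphens with spaces and
    collapse whitespace runs, so "Mono- e Digliceridi", "monoglycerides" and
    "farina integrale" all match their lexicon terms regardless of case,
    accents or hyphenation.
    """
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = text.lower().replace("-", " ")
    return re.sub(r"\s+", " ", text).strip()


@dataclass(frozen=True)
class QualitativeRule:
    """An ingredient-detection rule with polarity and category applicability.

    ``exclusions`` are normalised phrases removed from the text before term
    matching; they guard against a term firing inside a phrase the rule is
    not meant to cover (e.g. plain "corn starch" must never register as an
    alternative flour).
    """

    name: str
    polarity: Polarity
    lexicon: frozenset[str]
    applicable_categories: frozenset[Category]
    positional: bool = False
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        object.__setattr__(self, "lexicon",
                           frozenset(normalize(t) for t in self.lexicon))
        object.__setattr__(self, "exclusions",
                           frozenset(normalize(t) for t in self.exclusions))
        object.__setattr__(
            self, "applicable_categories",
            frozenset(Category(c) for c in self.applicable_categories))

    def applies_to(self, category: Category) -> bool:
        return Category(category) in self.applicable_categories


@dataclass(frozen=True)
class QualScore:
    """Presence flags and points for the rules applicable to one product.

    Rules not applicable to the product's category are omitted entirely —
    they are neither present/absent nor worth 0; reporting renders them as
    "n.u." (not used).
    """

    presence: dict[str, bool]
    points: dict[str, int]
    subtotal: int


_ALL = frozenset(Category)
_BREADLIKE = frozenset({Category.BREAD, Category.BREAD_SUBSTITUTES})
_SWEET = frozenset({Category.COOKIES, Category.BREAKFAST_PASTRIES})

#: Default bilingual lexicons.  Terms are matched as substrings of the
#: normalised ingredient string; multi-word legume terms require the flour
#: context because bare legume names ("pea", "soia") collide with unrelated
#: label text (peanut, soy lecithin).
DEFAULT_LEXICONS: dict[str, tuple[str, ...]] = {
    "starch_first": ("starch", "amido", "fecola"),
    "wholegrain_flours": ("wholegrain", "whole grain", "wholemeal",
                          "whole wheat", "integrale"),
    "sourdough": ("sourdough", "lievito madre", "pasta madre",
                  "pasta acida"),
    "legume_flours": ("legume flour", "soy flour", "farina di soia",
                      "lupin flour", "farina di lupino", "lupino",
                      "chickpea flour", "farina di ceci",
                      "pea flour", "farina di piselli",
                      "lentil flour", "farina di lenticchie",
                      "bean flour", "farina di fagioli"),
    "other_flours": ("buckwheat", "grano saraceno", "quinoa",
                     "amaranth", "amaranto", "sorghum", "sorgo",
                     "millet", "miglio", "teff", "rye", "segale",
                     "barley", "orzo"),
    "fructose": ("fructose", "fruttosio", "corn syrup",
                 "sciroppo di glucosio fruttosio",
                 "glucose fructose syrup", "fructose glucose syrup",
                 "high fructose corn syrup"),
    "emulsifiers": ("mono and diglycerides", "monoglycerides",
                    "diglycerides", "mono e digliceridi",
                    "monogliceridi", "digliceridi", "e471", "e 471"),
}

DEFAULT_APPLICABILITY: dict[str, frozenset[Category]] = {
    "starch_first": _ALL,
    "wholegrain_flours": frozenset(_BREADLIKE
                                   | {Category.BREAKFAST_PASTRIES}),
    "sourdough": frozenset({Category.BREAD}),
    "legume_flours": _BREADLIKE,
    "other_flours": _ALL,
    "fructose": _SWEET,
    "emulsifiers": _ALL,
}

_POLARITIES: dict[str, Polarity] = {
    "starch_first": Polarity.PRESENCE_SCORES_ZERO,
    "wholegrain_flours": Polarity.PRESENCE_SCORES_ONE,
    "sourdough": Polarity.PRESENCE_SCORES_ONE,
    "legume_flours": Polarity.PRESENCE_SCORES_ONE,
    "other_flours": Polarity.PRESENCE_SCORES_ONE,
    "fructose": Polarity.PRESENCE_SCORES_ZERO,
    "emulsifiers": Polarity.PRESENCE_SCORES_ZERO,
}

_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    # rice and corn are excluded from the alternative-flour rule by
    # definition; stripping them guards lexicon edits from ever matching
    # "corn flour" / "farina di riso".
    "other_flours": ("corn", "mais", "rice", "riso"),
}


def default_qualitative_rules(
        lexicons: dict[str, Iterable[str]] | None = None,
        applicability: dict[str, Iterable[Category]] | None = None,
) -> tuple[QualitativeRule, ...]:
    """The seven default rules; lexicons / applicability can be overridden.

    Overrides are per-rule: an omitted rule keeps its default lexicon and
    category set.
    """
    lex = dict(DEFAULT_LEXICONS)
    if lexicons:
        lex.update({k: tuple(v) for k, v in lexicons.items()})
    matrix = dict(DEFAULT_APPLICABILITY)
    if applicability:
        matrix.update({k: frozenset(Category(c) for c in v)
                       for k, v in applicability.items()})
    unknown = (set(lex) | set(matrix)) - set(RULE_NAMES)
    if unknown:
        raise ValueError(f"unknown qualitative rule(s): {sorted(unknown)}")
    return tuple(
        QualitativeRule(
            name=name,
            polarity=_POLARITIES[name],
            lexicon=frozenset(lex[name]),
            applicable_categories=matrix[name],
            positional=(name == "starch_first"),
            exclusions=frozenset(_EXCLUSIONS.get(name, ())),
        )
        for name in RULE_NAMES
    )


def _matches(rule: QualitativeRule, text: str) -> bool:
    text = normalize(text)
    for excl in rule.exclusions:
        text = text.replace(excl, " ")
    return any(term in text for term in rule.lexicon)


def detect(rule: QualitativeRule, ingredients: Sequence[str]) -> bool:
    """Whether the rule's ingredient is present in the (ordered) list.

    Positional rules inspect only the first — i.e. principal, lists being
    weight-ordered — ingredient; all others match anywhere in the list.
    """
    if not ingredients:
        raise ValueError("qualitative detection requires a non-empty "
                         "ingredient list")
    if rule.positional:
        return _matches(rule, ingredients[0])
    return any(_matches(rule, ing) for ing in ingredients)


def score_qualitative(product: Product,
                      rules: Sequence[QualitativeRule] | None = None,
                      ) -> QualScore:
    """Score the rules applicable to the product's category.

    A rule earns its point when the detected state matches its favourable
    polarity: presence for the flour/sourdough rules, absence for
    starch-first, fructose and emulsifiers.  Non-applicable rules are omitted
    from the result rather than scored 0.
    """
    if rules is None:
        rules = default_qualitative_rules()
    presence: dict[str, bool] = {}
    points: dict[str, int] = {}
    for rule in rules:
        if not rule.applies_to(product.category):
            continue
        found = detect(rule, product.ingredients)
        presence[rule.name] = found
        favourable = (found if rule.polarity is Polarity.PRESENCE_SCORES_ONE
                      else not found)
        points[rule.name] = 1 if favourable else 0
    return QualScore(presence=presence, points=points,
                     subtotal=sum(points.values()))
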