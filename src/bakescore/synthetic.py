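"""Seeded generator of synthetic GF/GC product markets.

No real product set is publicly deposited, so every pipeline stage is
exercised on synthetic markets: per-(category, group) segments with
parametric nutrient distributions (lognormal / truncated-normal / point
mass, g/100 g), a Beta-distributed saturated-fat fraction of total fat (so
``saturated_fat <= total_fat`` holds by construction), a probability of the
voluntary fiber declaration, and per-ingredient-rule presence probabilities.

Ingredient lists are assembled from lexicon exemplar terms so that detection
fires if and only if the generator's ground-truth flag is set; the
starch-first ground truth controls first-position placement, and filler
ingredients (water, salt, ...) are checked at generation time never to
collide with any rule lexicon.  Generation is deterministic given the seed:
each product draws from its own deterministic stream keyed by (seed,
category, group, index), so adding a segment never perturbs another
segment's draws.

``preset_reference_market`` returns a market spec shaped like a published
survey of Italian packaged bakery products: category/group sizes (GF 24,
26, 53, 32; GC 34, 49, 43, 36 for bread, bread substitutes, cookies and
breakfast pastries respectively) with nutrient levels and ingredient
frequencies loosely informed by its summary table — in particular,
gluten-free bread substitutes are formulated worse (less fiber, fewer
alternative flours, more emulsifiers) so their scores run stochastically
below the gluten-containing ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as sps

from .products import Category, GlutenGroup, NutritionFacts, Product
from .qualitative import (QualitativeRule, RULE_NAMES,
                          default_qualitative_rules, _matches)

__all__ = [
    "DistSpec", "SegmentSpec", "MarketSpec", "generate_market",
    "preset_reference_market", "null_market_spec", "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class DistSpec:
    """A non-negative nutrient amount distribution (g/100 g).

    Families: ``lognormal`` (params: median, sigma of log), ``truncnorm``
    (params: mu, sigma; truncated at 0) and ``point`` (params: value).
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family not in ("lognormal", "truncnorm", "point"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p)
                                                 for p in self.params))
        if self.family == "lognormal":
            median, sigma = self.params
            if median <= 0 or sigma <= 0:
                raise ValueError("lognormal needs median > 0, sigma > 0")
        elif self.family == "truncnorm":
            _, sigma = self.params
            if sigma <= 0:
                raise ValueError("truncnorm needs sigma > 0")
        elif self.params[0] < 0:
            raise ValueError("point mass must be non-negative")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "lognormal":
            median, sigma = self.params
            return float(median * math.exp(sigma * rng.standard_normal()))
        if self.family == "truncnorm":
            mu, sigma = self.params
            a = (0.0 - mu) / sigma
            return float(sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma,
                                           random_state=rng))
        return self.params[0]

    def prob_below(self, cutoff: float) -> float:
        """P(X < cutoff) — the implied frequency of a 'low X' claim."""
        if self.family == "lognormal":
            median, sigma = self.params
            if cutoff <= 0:
                return 0.0
            return float(sps.norm.cdf(math.log(cutoff / median) / sigma))
        if self.family == "truncnorm":
            mu, sigma = self.params
            a = (0.0 - mu) / sigma
            return float(sps.truncnorm.cdf(cutoff, a, np.inf, loc=mu,
                                           scale=sigma))
        return float(self.params[0] < cutoff)

    def prob_above(self, cutoff: float) -> float:
        return 1.0 - self.prob_below(cutoff)


@dataclass(frozen=True)
class SegmentSpec:
    """One (category, group) market segment."""

    n: int
    total_fat: DistSpec
    sodium: DistSpec
    sugars: DistSpec
    fiber: DistSpec
    #: Beta(a, b) parameters of saturated fat as a fraction of total fat.
    sat_fraction: tuple[float, float] = (2.0, 6.0)
    fiber_declared_p: float = 1.0
    #: rule name -> presence probability; omitted rules are never present.
    presence: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("segment size must be >= 0")
        a, b = self.sat_fraction
        if a <= 0 or b <= 0:
            raise ValueError("sat_fraction Beta parameters must be positive")
        probs = dict(self.presence)
        probs["_fiber_declared"] = self.fiber_declared_p
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name} = {p} outside [0, 1]")
        unknown = set(self.presence) - set(RULE_NAMES)
        if unknown:
            raise ValueError(f"unknown rule(s) in presence: {sorted(unknown)}")


@dataclass(frozen=True)
class MarketSpec:
    """A whole synthetic market: segments keyed by (category, group)."""

    segments: Mapping[tuple[Category, GlutenGroup], SegmentSpec]
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "segments", {
            (Category(c), GlutenGroup(g)): seg
            for (c, g), seg in self.segments.items()})

    def with_seed(self, seed: int) -> "MarketSpec":
        return replace(self, seed=seed)


# Exemplar label strings inserted when a rule's ground-truth flag is set.
# Each must trigger exactly its own rule; verified at generation time.
_EXEMPLARS: dict[str, str] = {
    "starch_first": "potato starch",
    "wholegrain_flours": "wholegrain flour",
    "sourdough": "sourdough",
    "legume_flours": "chickpea flour",
    "other_flours": "buckwheat flour",
    "fructose": "glucose fructose syrup",
    "emulsifiers": "mono and diglycerides of fatty acids",
}

#: Neutral first ingredient when starch is not first.
_NEUTRAL_FIRST = "rice flour"

#: Realistic fillers; must never collide with any rule lexicon.
_FILLERS = ("water", "sea salt", "sunflower oil", "yeast")


def _check_lexicon_collisions(rules: Iterable[QualitativeRule]) -> None:
    rules = list(rules)
    for filler in _FILLERS + (_NEUTRAL_FIRST,):
        hits = [r.name for r in rules if _matches(r, filler)]
        if hits:
            raise RuntimeError(
                f"filler ingredient {filler!r} collides with rule(s) {hits}")
    for name, exemplar in _EXEMPLARS.items():
        hits = {r.name for r in rules if _matches(r, exemplar)}
        if hits != {name}:
            raise RuntimeError(
                f"exemplar {exemplar!r} for {name} matches {sorted(hits)}")


def _segment_rng(seed: int, ci: int, gi: int, k: int) -> np.random.Generator:
    # Per-product stream: adding segments or products elsewhere never
    # perturbs this product's draws.
    return np.random.default_rng([seed & 0x7FFFFFFF, ci, gi, k])


def generate_market(spec: MarketSpec,
                    ) -> tuple[list[Product], dict[str, dict[str, bool]]]:
    """Generate products plus per-product ground-truth ingredient flags.

    Returns ``(products, truth)`` where ``truth[product_id][rule_name]`` is
    the flag the generator realised; qualitative detection on the generated
    ingredient list reproduces it exactly.
    """
    _check_lexicon_collisions(default_qualitative_rules())
    categories = list(Category)
    groups = list(GlutenGroup)
    products: list[Product] = []
    truth: dict[str, dict[str, bool]] = {}
    for (category, group), seg in spec.segments.items():
        ci, gi = categories.index(category), groups.index(group)
        for k in range(seg.n):
            rng = _segment_rng(spec.seed, ci, gi, k)
            pid = f"{category.value}-{group.value}-{k:04d}"
            total_fat = seg.total_fat.sample(rng)
            sat = total_fat * float(rng.beta(*seg.sat_fraction))
            sodium = seg.sodium.sample(rng)
            sugars = seg.sugars.sample(rng)
            fiber = (seg.fiber.sample(rng)
                     if rng.random() < seg.fiber_declared_p else None)
            flags = {name: bool(rng.random() < seg.presence.get(name, 0.0))
                     for name in RULE_NAMES}
            ingredients = [_EXEMPLARS["starch_first"]
                           if flags["starch_first"] else _NEUTRAL_FIRST]
            ingredients += [_EXEMPLARS[name] for name in RULE_NAMES
                            if name != "starch_first" and flags[name]]
            ingredients += list(_FILLERS[:2 + int(rng.integers(3))])
            facts = NutritionFacts(total_fat=round(total_fat, 2),
                                   saturated_fat=round(min(sat, total_fat), 2),
                                   sodium=round(sodium, 3),
                                   sugars=round(sugars, 2),
                                   fiber=None if fiber is None
                                   else round(fiber, 2))
            products.append(Product(id=pid, category=category, group=group,
                                    facts=facts,
                                    ingredients=tuple(ingredients)))
            truth[pid] = flags
    return products, truth


def write_ground_truth(truth: dict[str, dict[str, bool]], path) -> None:
    """Write the generator's ground-truth flags to a JSON sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path) -> dict[str, dict[str, bool]]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _seg(n, fat, sodium, sugars, fiber, sat=(2.0, 6.0), fdecl=0.95,
         **presence) -> SegmentSpec:
    return SegmentSpec(
        n=n,
        total_fat=DistSpec("lognormal", fat),
        sodium=DistSpec("lognormal", sodium),
        sugars=DistSpec("lognormal", sugars),
        fiber=DistSpec("lognormal", fiber),
        sat_fraction=sat,
        fiber_declared_p=fdecl,
        presence=presence,
    )


def preset_reference_market(seed: int = 0) -> MarketSpec:
    """Market spec shaped like the surveyed Italian GF/GC bakery market.

    Segment sizes follow the survey's per-category sample sizes; nutrient
    medians and ingredient frequencies are loosely informed by its condition
    table.  The gluten-free bread-substitute segment is formulated worse
    than its counterpart (less fiber, fewer alternative flours, more
    emulsifiers, starch first), so its scores run stochastically lower.
    """
    C, G = Category, GlutenGroup
    segments = {
        (C.BREAD, G.GC): _seg(
            34, (4.0, 0.45), (0.45, 0.35), (4.0, 0.5), (4.0, 0.5),
            starch_first=0.00, wholegrain_flours=0.38, sourdough=0.21,
            legume_flours=0.12, other_flours=0.47, emulsifiers=0.15),
        (C.BREAD, G.GF): _seg(
            24, (4.5, 0.5), (0.40, 0.35), (4.0, 0.5), (4.5, 0.55),
            starch_first=0.58, wholegrain_flours=0.45, sourdough=0.54,
            legume_flours=0.08, other_flours=0.79, emulsifiers=0.63),
        (C.BREAD_SUBSTITUTES, G.GC): _seg(
            49, (9.0, 0.5), (0.50, 0.35), (3.0, 0.6), (4.5, 0.45),
            starch_first=0.02, wholegrain_flours=0.16, legume_flours=0.02,
            other_flours=0.47, emulsifiers=0.08),
        (C.BREAD_SUBSTITUTES, G.GF): _seg(
            26, (13.0, 0.45), (0.65, 0.35), (3.5, 0.6), (2.2, 0.5),
            starch_first=0.77, wholegrain_flours=0.02, legume_flours=0.19,
            other_flours=0.27, emulsifiers=0.59),
        (C.COOKIES, G.GC): _seg(
            43, (18.0, 0.3), (0.25, 0.4), (22.0, 0.25), (3.0, 0.5),
            sat=(4.0, 4.0),
            starch_first=0.02, other_flours=0.07, fructose=0.28,
            emulsifiers=0.12),
        (C.COOKIES, G.GF): _seg(
            53, (19.0, 0.3), (0.28, 0.4), (23.0, 0.25), (3.0, 0.5),
            sat=(4.0, 4.0),
            starch_first=0.42, other_flours=0.49, fructose=0.06,
            emulsifiers=0.28),
        (C.BREAKFAST_PASTRIES, G.GC): _seg(
            36, (15.0, 0.3), (0.30, 0.4), (24.0, 0.25), (3.0, 0.5),
            sat=(4.0, 4.0),
            starch_first=0.03, wholegrain_flours=0.00, other_flours=0.53,
            fructose=0.08, emulsifiers=0.89),
        (C.BREAKFAST_PASTRIES, G.GF): _seg(
            32, (16.0, 0.3), (0.32, 0.4), (25.0, 0.25), (3.0, 0.5),
            sat=(4.0, 4.0),
            starch_first=0.38, wholegrain_flours=0.28, other_flours=0.28,
            fructose=0.19, emulsifiers=0.63),
    }
    return MarketSpec(segments=segments, seed=seed)


def null_market_spec(n_gf: int = 20, n_gc: int = 20, seed: int = 0,
                     category: Category = Category.BREAD) -> MarketSpec:
    """Both groups drawn from one identical distribution — a null market
    for calibration studies (type-I error of the comparison pipeline)."""
    def seg(n):
        return _seg(n, (5.0, 0.6), (0.35, 0.5), (4.5, 0.7), (3.0, 0.6),
                    starch_first=0.5, wholegrain_flours=0.4, sourdough=0.3,
                    legume_flours=0.2, other_flours=0.5, fructose=0.2,
                    emulsifiers=0.4)
    return MarketSpec(
        segments={(category, GlutenGroup.GF): seg(n_gf),
                  (category, GlutenGroup.GC): seg(n_gc)},
        seed=seed)
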