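"""Quantitative sub-score: tiered points for five labelled nutrients.

Five nutrients — total fat, saturated fat, sodium, fiber and sugars, all per
100 g — are scored 0, 1 or 2 points against the claim thresholds of
Regulation (EC) No 1924/2006 ("low fat", "low saturated fat", "low sodium" /
"very low sodium", "source of fibre", "low sugars" / "sugars-free").  The
tier table is::

    total_fat      < 3     -> 1 point            (low fat)
    saturated_fat  < 1.5   -> 1 point            (low saturated fat)
    sodium         < 0.4   -> 1, < 0.12 -> 2     (low / very low sodium)
    fiber          > 3     -> 1 point            (source of fibre)
    sugars         < 5     -> 1, < 0.05 -> 2     (low sugar / sugar-free)

so the sub-score ranges 0–7.  Cut-offs are strict inequalities by default
(values exactly at a cut-off score the unfavourable tier); a config switch
selects regulation-style inclusive semantics instead.  The sugar-free cut-off
defaults to 0.05 g/100 g as in the source rubric; the regulation's own
"sugars-free" threshold is 0.5 g/100 g and can be selected via
``sugar_free_cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .products import NutritionFacts, SALT_TO_SODIUM_FACTOR

#: Maximum attainable quantitative sub-score under the default rules.
MAX_QUANT_SCORE = 7


class Direction(str, Enum):
    LOWER_IS_BETTER = "lower_is_better"
    HIGHER_IS_BETTER = "higher_is_better"


@dataclass(frozen=True)
class ThresholdRule:
    """A tiered nutrient -> points mapping.

    ``tiers`` is ordered from least to most favourable: each entry is a
    ``(cutoff, points)`` pair and a value earns the points of the most
    favourable tier whose condition it satisfies.
    """

    parameter: str
    direction: Direction
    tiers: tuple[tuple[float, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "tiers",
                           tuple((float(c), int(p)) for c, p in self.tiers))
        pts = [p for _, p in self.tiers]
        if pts != sorted(pts) or any(p < 0 for p in pts):
            raise ValueError(f"{self.parameter}: tier points must be "
                             "non-negative and non-decreasing in favourability")
        cuts = [c for c, _ in self.tiers]
        ordered = (cuts == sorted(cuts, reverse=True)
                   if self.direction is Direction.LOWER_IS_BETTER
                   else cuts == sorted(cuts))
        if len(set(cuts)) != len(cuts) or not ordered:
            raise ValueError(f"{self.parameter}: cutoffs must be strictly "
                             "ordered in the favourable direction")

    @property
    def max_points(self) -> int:
        return max(p for _, p in self.tiers)

    def points_for(self, value: float, *, inclusive: bool = False) -> int:
        """Points earned by ``value``: the most favourable satisfied tier.

        ``inclusive=True`` treats cut-offs as attainable ("no more than" /
        "at least"); the default is strict comparison.
        """
        best = 0
        for cutoff, points in self.tiers:
            if self.direction is Direction.LOWER_IS_BETTER:
                ok = value <= cutoff if inclusive else value < cutoff
            else:
                ok = value >= cutoff if inclusive else value > cutoff
            if ok:
                best = max(best, points)
        return best


@dataclass(frozen=True)
class QuantScore:
    """Per-nutrient point breakdown plus the EU-claim condition flags."""

    points: dict[str, int]
    low_fat: bool
    low_saturated_fat: bool
    low_sodium: bool
    very_low_sodium_tier: bool
    source_of_fiber: bool
    low_sugar: bool
    sugar_free_tier: bool
    subtotal: int

    def flag(self, name: str) -> bool:
        return bool(getattr(self, name))


def default_rules(sugar_free_cutoff: float = 0.05) -> tuple[ThresholdRule, ...]:
    """The five default threshold rules (claim limits of Reg 1924/2006).

    ``sugar_free_cutoff`` selects the top sugar tier: 0.05 g/100 g by default,
    0.5 g/100 g for the regulation's printed "sugars-free" limit.
    """
    return (
        ThresholdRule("total_fat", Direction.LOWER_IS_BETTER, ((3.0, 1),)),
        ThresholdRule("saturated_fat", Direction.LOWER_IS_BETTER, ((1.5, 1),)),
        ThresholdRule("sodium", Direction.LOWER_IS_BETTER,
                      ((0.4, 1), (0.12, 2))),
        ThresholdRule("fiber", Direction.HIGHER_IS_BETTER, ((3.0, 1),)),
        ThresholdRule("sugars", Direction.LOWER_IS_BETTER,
                      ((5.0, 1), (sugar_free_cutoff, 2))),
    )


def score_quantitative(facts: NutritionFacts,
                       rules: tuple[ThresholdRule, ...] | None = None,
                       *, inclusive: bool = False) -> QuantScore:
    """Score nutrition facts under the tier scheme.

    An undeclared fiber value scores 0 fiber points (``source_of_fiber``
    false) — fiber declaration is voluntary, so absence is tolerated rather
    than an error.  Any other nutrient a rule references must be present.
    """
    if rules is None:
        rules = default_rules()
    points: dict[str, int] = {}
    for rule in rules:
        value = getattr(facts, rule.parameter, None)
        if value is None:
            if rule.parameter == "fiber":
                points["fiber"] = 0
                continue
            raise ValueError(f"nutrition facts lack required parameter "
                             f"{rule.parameter!r}")
        points[rule.parameter] = rule.points_for(value, inclusive=inclusive)

    sodium_pts = points.get("sodium", 0)
    sugar_pts = points.get("sugars", 0)
    return QuantScore(
        points=points,
        low_fat=points.get("total_fat", 0) >= 1,
        low_saturated_fat=points.get("saturated_fat", 0) >= 1,
        low_sodium=sodium_pts >= 1,
        very_low_sodium_tier=sodium_pts >= 2,
        source_of_fiber=points.get("fiber", 0) >= 1,
        low_sugar=sugar_pts >= 1,
        sugar_free_tier=sugar_pts >= 2,
        subtotal=sum(points.values()),
    )


def salt_equivalent(sodium: float) -> float:
    """Salt amount (g/100 g) equivalent to a sodium amount: sodium x 2.5."""
    if sodium < 0:
        raise ValueError(f"sodium must be >= 0, got {sodium}")
    return sodium * SALT_TO_SODIUM_FACTOR
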