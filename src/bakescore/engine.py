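"""Score engine: combine the two sub-scores into a product total.

A product's total score is the quantitative sub-score (0–7 nutrient points)
plus the qualitative sub-score (0/1 point per applicable ingredient rule).
Because the number of applicable qualitative rules differs by category, so
does the ceiling: 7 + |applicable rules| — bread 13, bread substitutes 12,
breakfast pastries 12, cookies 11 under the default matrix.  A ``normalized``
fraction (total / ceiling) is provided as a convenience for cross-category
comparison; it is an extension beyond the original rubric and is excluded
from rubric-replication outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import ScoringConfig
from .products import Category, Product
from .qualitative import QualScore, score_qualitative
from .quantitative import MAX_QUANT_SCORE, QuantScore, score_quantitative

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreResult:
    """Full per-product scoring breakdown."""

    product_id: str
    category: Category
    group: str
    quant: QuantScore
    qual: QualScore | None
    total: int
    category_max: int

    @property
    def normalized(self) -> float:
        return self.total / self.category_max


@dataclass(frozen=True)
class BatchOutcome:
    """Results plus per-product failures collected in lenient mode."""

    results: list[ScoreResult]
    failures: list[tuple[str, Exception]]


def category_max(category: Category,
                 config: ScoringConfig | None = None) -> int:
    """Score ceiling for a category: 7 + number of applicable rules."""
    config = config or ScoringConfig()
    category = Category(category)
    n_rules = sum(rule.applies_to(category)
                  for rule in config.qualitative_rules())
    if config.quantitative_only:
        return MAX_QUANT_SCORE
    return MAX_QUANT_SCORE + n_rules


def score_product(product: Product,
                  config: ScoringConfig | None = None) -> ScoreResult:
    """Score one product; deterministic in (product, config).

    In quantitative-only mode the ingredient list is ignored (and may be
    empty); otherwise an empty list is an error because the qualitative
    rules cannot be evaluated.
    """
    config = config or ScoringConfig()
    quant = score_quantitative(product.facts, config.threshold_rules(),
                               inclusive=config.inclusive)
    if config.quantitative_only:
        qual = None
        total = quant.subtotal
    else:
        if not product.ingredients:
            raise ValueError(
                f"product {product.id!r} has an empty ingredient list; "
                "use quantitative-only mode to score it")
        qual = score_qualitative(product, config.qualitative_rules())
        total = quant.subtotal + qual.subtotal
    return ScoreResult(
        product_id=product.id,
        category=product.category,
        group=product.group.value,
        quant=quant,
        qual=qual,
        total=total,
        category_max=category_max(product.category, config),
    )


def score_batch(products, config: ScoringConfig | None = None,
                ) -> BatchOutcome:
    """Score a product sequence, preserving input order.

    Lenient by default: per-product failures are collected and reported
    without aborting the batch.  ``config.strict_batch`` re-raises the first
    failure instead.
    """
    config = config or ScoringConfig()
    results: list[ScoreResult] = []
    failures: list[tuple[str, Exception]] = []
    for product in products:
        try:
            results.append(score_product(product, config))
        except Exception as err:  # noqa: BLE001 - collected per contract
            if config.strict_batch:
                raise
            failures.append((product.id, err))
            logger.warning("scoring failed for %r: %s", product.id, err)
    return BatchOutcome(results=results, failures=failures)


def results_to_frame(results) -> pd.DataFrame:
    """Tabulate score results: one row per product with every per-parameter
    point, claim/presence flag, subtotal, total and ceiling."""
    rows = []
    for r in results:
        row: dict = {
            "id": r.product_id,
            "category": r.category.value,
            "group": r.group,
        }
        row.update({f"pts_{k}": v for k, v in r.quant.points.items()})
        for flag in ("low_fat", "low_saturated_fat", "low_sodium",
                     "very_low_sodium_tier", "source_of_fiber", "low_sugar",
                     "sugar_free_tier"):
            row[flag] = r.quant.flag(flag)
        row["quant_subtotal"] = r.quant.subtotal
        if r.qual is not None:
            row.update({f"has_{k}": v for k, v in r.qual.presence.items()})
            row.update({f"qpts_{k}": v for k, v in r.qual.points.items()})
            row["qual_subtotal"] = r.qual.subtotal
        row["total"] = r.total
        row["category_max"] = r.category_max
        rows.append(row)
    return pd.DataFrame(rows)
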