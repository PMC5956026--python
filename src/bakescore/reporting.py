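"""Reporting surfaces: condition-match percentage tables and box summaries.

Two presentation surfaces are produced from a scored product set:

* a condition table — for every (category, group) cell, the percentage of
  products matching each claim condition (low fat, low saturated fat, low
  sodium, source of fiber, sugar free, low sugar) and each ingredient
  condition (starch as first ingredient, wholegrain flours, sourdough, flour
  from legumes, other flours, fructose, emulsifiers).  Ingredient columns
  report raw presence, independent of scoring polarity; a condition that is
  not applicable to a category carries the distinguished marker ``"n.u."``
  (not used), which is not the same as 0 %.  Percentages are rounded to whole
  numbers, half away from zero.

* per-(category, group) five-number summaries of the total score (min, Q1,
  median, Q3, max; quartiles by linear interpolation), suitable for box
  plots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ScoringConfig
from .engine import ScoreResult
from .products import Category, GlutenGroup, Product

logger = logging.getLogger(__name__)

#: Marker for a condition column that does not apply to a category.
NOT_USED = "n.u."

#: Claim columns -> QuantScore flag names, in presentation order.
CLAIM_COLUMNS = {
    "low_fat": "low_fat",
    "low_saturated_fat": "low_saturated_fat",
    "low_sodium": "low_sodium",
    "source_of_fiber": "source_of_fiber",
    "sugar_free": "sugar_free_tier",
    "low_sugar": "low_sugar",
}

#: Ingredient presence columns, in presentation order.
INGREDIENT_COLUMNS = (
    "starch_first",
    "wholegrain_flours",
    "sourdough",
    "legume_flours",
    "other_flours",
    "fructose",
    "emulsifiers",
)

KEY_COLUMNS = ("category", "group", "n")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ConditionReport:
    """Percentage-of-products-matching table; rows keyed by (category, group).

    ``frame`` holds one row per (category, group) with ``n`` and one column
    per condition; cells are integer percentages or the ``"n.u."`` marker.
    """

    frame: pd.DataFrame

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConditionReport):
            return NotImplemented
        return self.frame.equals(other.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionReport":
        frame = pd.read_csv(path, dtype=str)
        for col in frame.columns:
            if col in ("category", "group"):
                continue
            frame[col] = [c if c == NOT_USED else int(c)
                          for c in frame[col]]
        return cls(frame=frame)


def condition_report(products: Sequence[Product],
                     results: Sequence[ScoreResult],
                     config: ScoringConfig | None = None) -> ConditionReport:
    """Build the condition-match percentage table from scored products.

    Ingredient columns count detected presence (not points), so
    "starch_first = 58" means 58 % of that cell's products list a starch
    first even though having it earns no point.
    """
    config = config or ScoringConfig()
    by_id = {r.product_id: r for r in results}
    missing = [p.id for p in products if p.id not in by_id]
    if missing or len(results) != len(products):
        raise ValueError("results do not cover the product set "
                         f"(missing or extra ids, e.g. {missing[:3]})")
    applicable = {
        rule.name: rule.applicable_categories
        for rule in config.qualitative_rules()
    }

    rows = []
    for category in Category:
        cell_groups = {}
        for group in GlutenGroup:
            cell = [by_id[p.id] for p in products
                    if p.category is category and p.group is group]
            cell_groups[group] = cell
        present = {g for g, cell in cell_groups.items() if cell}
        if present and len(present) < len(cell_groups):
            absent = set(cell_groups) - present
            logger.info("category %s: no products in group(s) %s; "
                        "row omitted", category.value,
                        sorted(g.value for g in absent))
        for group in GlutenGroup:
            cell = cell_groups[group]
            if not cell:
                continue
            n = len(cell)
            row: dict = {"category": category.value, "group": group.value,
                         "n": n}
            for col, flag in CLAIM_COLUMNS.items():
                count = sum(r.quant.flag(flag) for r in cell)
                row[col] = _round_half_away(100.0 * count / n)
            for col in INGREDIENT_COLUMNS:
                if category not in applicable[col]:
                    row[col] = NOT_USED
                    continue
                count = sum(r.qual.presence[col] for r in cell
                            if r.qual is not None)
                row[col] = _round_half_away(100.0 * count / n)
            rows.append(row)
    columns = list(KEY_COLUMNS) + list(CLAIM_COLUMNS) + list(
        INGREDIENT_COLUMNS)
    return ConditionReport(frame=pd.DataFrame(rows, columns=columns))


def score_summary(results: Sequence[ScoreResult]) -> pd.DataFrame:
    """Five-number summary of total scores per (category, group).

    Quartiles use the linear-interpolation convention (numpy default), the
    one most plotting libraries draw box plots with.
    """
    if not results:
        raise ValueError("score_summary requires at least one result")
    rows = []
    for category in Category:
        for group in GlutenGroup:
            scores = [r.total for r in results
                      if r.category is category and r.group == group.value]
            if not scores:
                continue
            q0, q1, q2, q3, q4 = np.percentile(
                scores, [0, 25, 50, 75, 100], method="linear")
            rows.append({
                "category": category.value, "group": group.value,
                "n": len(scores), "min": q0, "q1": q1, "median": q2,
                "q3": q3, "max": q4,
            })
    return pd.DataFrame(rows)


def _to_markdown(frame: pd.DataFrame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def render(report, format: str, path) -> Path:
    """Serialize a report deterministically.

    ``report`` is a :class:`ConditionReport` or a summary ``DataFrame``;
    ``format`` is ``csv``, ``markdown`` or (for summaries) ``plot`` — a box
    plot drawn from the five-number summaries.
    """
    path = Path(path)
    frame = report.frame if isinstance(report, ConditionReport) else report
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "markdown":
        path.write_text(_to_markdown(frame), encoding="utf-8")
    elif format == "plot":
        if isinstance(report, ConditionReport):
            raise ValueError("plot rendering applies to score summaries")
        _render_boxplot(frame, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _render_boxplot(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    boxes = [{
        "label": f"{row['category']}\n{row['group']}",
        "whislo": row["min"], "q1": row["q1"], "med": row["median"],
        "q3": row["q3"], "whishi": row["max"], "fliers": [],
    } for _, row in summary.iterrows()]
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(boxes)), 4))
    ax.bxp(boxes, showfliers=False)
    ax.set_ylabel("total score (points)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
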