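"""Domain types for packaged bakery products and validated CSV/JSON ingestion.

A :class:`Product` is one packaged item: a food category, a gluten group
(gluten-free ``GF`` or gluten-containing ``GC``), per-100 g nutrition facts
and the on-pack ingredient list in descending weight order.  Labels may
declare either sodium or salt; salt is normalised to sodium with the standard
regulatory equivalence salt = sodium x 2.5 at ingestion time, and the declared
salt value is retained so that files round-trip field-for-field.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Regulatory salt/sodium equivalence factor (salt = sodium * 2.5).
SALT_TO_SODIUM_FACTOR = 2.5

#: Separator used for the ingredient column in CSV files.  On-pack lists use
#: commas internally, so the column is ";"-joined.
INGREDIENT_SEPARATOR = ";"

CSV_COLUMNS = [
    "id",
    "brand",
    "category",
    "group",
    "total_fat",
    "saturated_fat",
    "sodium",
    "salt",
    "fiber",
    "sugars",
    "ingredients",
]


class Category(str, Enum):
    """The four food categories products are grouped into."""

    BREAD = "bread"
    BREAD_SUBSTITUTES = "bread_substitutes"
    COOKIES = "cookies"
    BREAKFAST_PASTRIES = "breakfast_pastries"


class GlutenGroup(str, Enum):
    """Gluten-free vs gluten-containing product group."""

    GF = "GF"
    GC = "GC"


class ValidationError(ValueError):
    """A product record violates a domain invariant.

    Carries the offending record id / row and field name so batch ingestion
    can report exactly which record was rejected and why.
    """

    def __init__(self, message: str, *, record: str | int | None = None,
                 field_name: str | None = None):
        self.record = record
        self.field_name = field_name
        prefix = ""
        if record is not None:
            prefix += f"record {record!r}: "
        if field_name is not None:
            prefix += f"field {field_name!r}: "
        super().__init__(prefix + message)


@dataclass(frozen=True)
class NutritionFacts:
    """Per-100 g nutrition facts as declared on the pack label.

    Exactly one of ``sodium`` / ``salt`` must be declared; a declared salt
    value is converted to sodium (``salt / 2.5``) and kept alongside.  Fiber
    declaration is voluntary under EU labelling rules, so ``fiber=None``
    (undeclared) is distinct from ``fiber=0.0``.
    """

    total_fat: float
    saturated_fat: float
    sugars: float
    sodium: float | None = None
    salt: float | None = None
    fiber: float | None = None

    def __post_init__(self):
        if self.sodium is None and self.salt is None:
            raise ValidationError("one of sodium or salt must be declared",
                                  field_name="sodium")
        if self.sodium is not None and self.salt is not None:
            # Both present is allowed only when consistent (e.g. after a
            # round-trip); anything else is an over-declaration error.
            if abs(self.salt - self.sodium * SALT_TO_SODIUM_FACTOR) > 1e-9:
                raise ValidationError(
                    "sodium and salt both declared but inconsistent "
                    f"({self.sodium} vs {self.salt}/2.5)",
                    field_name="salt")
        if self.sodium is None:
            object.__setattr__(self, "sodium",
                               self.salt / SALT_TO_SODIUM_FACTOR)
        for name in ("total_fat", "saturated_fat", "sugars", "sodium",
                     "salt", "fiber"):
            value = getattr(self, name)
            if value is not None and not value >= 0:
                raise ValidationError(f"must be >= 0, got {value}",
                                      field_name=name)
        if self.saturated_fat > self.total_fat + 1e-9:
            raise ValidationError(
                f"saturated_fat ({self.saturated_fat}) exceeds total_fat "
                f"({self.total_fat})", field_name="saturated_fat")


@dataclass(frozen=True)
class Product:
    """One packaged bakery product."""

    id: str
    category: Category
    group: GlutenGroup
    facts: NutritionFacts
    ingredients: tuple[str, ...] = ()
    brand: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "group", GlutenGroup(self.group))
        object.__setattr__(self, "ingredients",
                           tuple(s.strip() for s in self.ingredients))
        if any(not s for s in self.ingredients):
            raise ValidationError("empty ingredient string",
                                  record=self.id, field_name="ingredients")


def _parse_float(raw, *, record, field_name) -> float | None:
    if raw is None or raw == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"not a number: {raw!r}", record=record,
                              field_name=field_name) from None
    if value < 0:
        raise ValidationError(f"negative nutrient value {value}",
                              record=record, field_name=field_name)
    return value


def _record_to_product(rec: dict, record_label) -> Product:
    for required in ("id", "category", "group", "total_fat",
                     "saturated_fat", "sugars"):
        if rec.get(required) in (None, ""):
            raise ValidationError("missing mandatory field",
                                  record=record_label, field_name=required)
    try:
        category = Category(rec["category"])
    except ValueError:
        raise ValidationError(f"unknown category {rec['category']!r}",
                              record=record_label,
                              field_name="category") from None
    try:
        group = GlutenGroup(rec["group"])
    except ValueError:
        raise ValidationError(f"unknown group {rec['group']!r}",
                              record=record_label,
                              field_name="group") from None

    ingredients = rec.get("ingredients") or []
    if isinstance(ingredients, str):
        ingredients = [s for s in ingredients.split(INGREDIENT_SEPARATOR)
                       if s.strip()]
    try:
        facts = NutritionFacts(
            total_fat=_parse_float(rec["total_fat"], record=record_label,
                                   field_name="total_fat"),
            saturated_fat=_parse_float(rec["saturated_fat"],
                                       record=record_label,
                                       field_name="saturated_fat"),
            sugars=_parse_float(rec["sugars"], record=record_label,
                                field_name="sugars"),
            sodium=_parse_float(rec.get("sodium"), record=record_label,
                                field_name="sodium"),
            salt=_parse_float(rec.get("salt"), record=record_label,
                              field_name="salt"),
            fiber=_parse_float(rec.get("fiber"), record=record_label,
                               field_name="fiber"),
        )
        return Product(id=str(rec["id"]), category=category, group=group,
                       facts=facts, ingredients=tuple(ingredients),
                       brand=rec.get("brand") or None)
    except ValidationError as err:
        if err.record is None:
            raise ValidationError(str(err), record=record_label) from err
        raise


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; "
                     "pass format='csv' or 'json'")


def read_products(path, format: str | None = None, *,
                  on_error: str = "raise") -> list[Product]:
    """Read and validate products from a CSV or JSON file.

    Parameters
    ----------
    path : path-like
        Input file.  CSV must carry the documented column set; JSON must be a
        list of objects with the same fields and ``ingredients`` as an array.
    format : {"csv", "json"}, optional
        Inferred from the file suffix when omitted.
    on_error : {"raise", "collect"}
        ``"raise"`` aborts on the first invalid record; ``"collect"`` skips
        invalid records, logs each rejected row number, and returns the valid
        remainder.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise ValidationError("JSON root must be a list of products")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    products: list[Product] = []
    rejected: list[tuple[int, ValidationError]] = []
    for i, rec in enumerate(rows, start=1):
        try:
            products.append(_record_to_product(rec, rec.get("id") or f"row {i}"))
        except ValidationError as err:
            if on_error == "raise":
                raise
            rejected.append((i, err))
            logger.warning("rejected record at row %d: %s", i, err)
    if rejected:
        logger.warning("%d of %d records rejected", len(rejected), len(rows))
    return products


def _product_to_record(p: Product) -> dict:
    facts = p.facts
    # Preserve the declared form: if salt was declared, write salt; the
    # normalised sodium is written either way so files are self-contained.
    return {
        "id": p.id,
        "brand": p.brand,
        "category": p.category.value,
        "group": p.group.value,
        "total_fat": facts.total_fat,
        "saturated_fat": facts.saturated_fat,
        "sodium": facts.sodium,
        "salt": facts.salt,
        "fiber": facts.fiber,
        "sugars": facts.sugars,
        "ingredients": list(p.ingredients),
    }


def write_products(products: Iterable[Product], path,
                   format: str | None = None) -> None:
    """Write products to CSV or JSON such that :func:`read_products`
    reproduces them field-for-field, including ingredient order."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records = [_product_to_record(p) for p in products]
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for rec in records:
                rec = dict(rec)
                rec["ingredients"] = INGREDIENT_SEPARATOR.join(
                    rec["ingredients"])
                writer.writerow({k: ("" if v is None else v)
                                 for k, v in rec.items()})
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1, ensure_ascii=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def salt_to_sodium(salt: float) -> float:
    """Convert a declared salt amount (g/100 g) to sodium (g/100 g)."""
    if salt < 0:
        raise ValidationError(f"salt must be >= 0, got {salt}",
                              field_name="salt")
    return salt / SALT_TO_SODIUM_FACTOR
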