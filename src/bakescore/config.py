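"""Scoring configuration: rules-as-data with YAML load/save.

Everything tunable about the rubric lives here so alternative profiles can
be expressed without code change: the quantitative tier table, the boundary
semantics at a cut-off, the sugar-free cut-off, the qualitative lexicons and
the category-applicability matrix, plus the statistical settings (alpha,
exact-test threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .products import Category
from .qualitative import QualitativeRule, default_qualitative_rules
from .quantitative import ThresholdRule, default_rules


@dataclass(frozen=True)
class ScoringConfig:
    """Active rubric + statistics settings.

    Parameters
    ----------
    boundary : {"strict", "inclusive"}
        How values sitting exactly on a cut-off are treated.  ``"strict"``
        (default) scores them in the unfavourable tier, matching the printed
        strict inequalities of the rubric; ``"inclusive"`` uses the
        regulation's "no more than"/"at least" reading.
    sugar_free_cutoff : float
        Top sugar tier in g/100 g: 0.05 by default, 0.5 for the regulation's
        "sugars-free" limit.
    quantitative_only : bool
        Score products from nutrition facts alone (sensitivity-analysis
        mode); ingredient lists may then be empty.
    strict_batch : bool
        Batch scoring re-raises the first per-product failure instead of
        collecting failures.
    alpha : float
        Significance level for group comparisons.
    exact_threshold : int
        Mann-Whitney switches from exact enumeration to the tie-corrected
        normal approximation above this combined sample size.
    """

    boundary: str = "strict"
    sugar_free_cutoff: float = 0.05
    quantitative_only: bool = False
    strict_batch: bool = False
    alpha: float = 0.05
    exact_threshold: int = 16
    continuity_correction: bool = True
    lexicons: dict | None = None
    applicability: dict | None = None
    quant_rules: tuple[ThresholdRule, ...] | None = None
    # memo for built rule objects; identity-irrelevant, excluded from eq/repr
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if self.boundary not in ("strict", "inclusive"):
            raise ValueError("boundary must be 'strict' or 'inclusive'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sugar_free_cutoff <= 0:
            raise ValueError("sugar_free_cutoff must be positive")

    @property
    def inclusive(self) -> bool:
        return self.boundary == "inclusive"

    def threshold_rules(self) -> tuple[ThresholdRule, ...]:
        if self.quant_rules is not None:
            return self.quant_rules
        if "quant" not in self._cache:
            self._cache["quant"] = default_rules(
                sugar_free_cutoff=self.sugar_free_cutoff)
        return self._cache["quant"]

    def qualitative_rules(self) -> tuple[QualitativeRule, ...]:
        if "qual" not in self._cache:
            self._cache["qual"] = default_qualitative_rules(
                lexicons=self.lexicons, applicability=self.applicability)
        return self._cache["qual"]


def load_config(path) -> ScoringConfig:
    """Load a :class:`ScoringConfig` from a YAML file.

    Recognised keys mirror the dataclass fields; ``quant_rules`` is a list of
    ``{parameter, direction, tiers: [[cutoff, points], ...]}`` mappings and
    ``applicability`` maps rule names to category lists.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "quant_rules" in raw and raw["quant_rules"] is not None:
        raw["quant_rules"] = tuple(
            ThresholdRule(r["parameter"], r["direction"],
                          tuple((t[0], t[1]) for t in r["tiers"]))
            for r in raw["quant_rules"])
    return ScoringConfig(**raw)


def save_config(config: ScoringConfig, path) -> None:
    """Write the config to YAML (round-trips through :func:`load_config`)."""
    raw: dict = {
        "boundary": config.boundary,
        "sugar_free_cutoff": config.sugar_free_cutoff,
        "quantitative_only": config.quantitative_only,
        "strict_batch": config.strict_batch,
        "alpha": config.alpha,
        "exact_threshold": config.exact_threshold,
        "continuity_correction": config.continuity_correction,
        "lexicons": ({k: list(v) for k, v in config.lexicons.items()}
                     if config.lexicons else None),
        "applicability": ({k: [Category(c).value for c in v]
                           for k, v in config.applicability.items()}
                          if config.applicability else None),
        "quant_rules": ([{"parameter": r.parameter,
                          "direction": r.direction.value,
                          "tiers": [list(t) for t in r.tiers]}
                         for r in config.quant_rules]
                        if config.quant_rules else None),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
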