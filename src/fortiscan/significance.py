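"""Nutrient-significance rules of the EU labeling legislation.

A declared amount is *significant* when it reaches 7.5 % of the adult daily
reference intake per 100 mL for beverages, or 15 % per 100 g for other foods.
Equality counts as significant.  Beverage membership is purely categorical:
a configured set of food groups and subgroups, never inferred from names.
"""

from __future__ import annotations

from .config import BeverageRule
from .model import BrandedFoodRecord, NutrientSpec

BEVERAGE_FRACTION = 0.075
SOLID_FRACTION = 0.15


def is_beverage(record: BrandedFoodRecord, rule: BeverageRule) -> bool:
    if record.food_group is not None and record.food_group in rule.beverage_food_groups:
        return True
    return (
        record.food_subgroup is not None
        and record.food_subgroup in rule.beverage_subgroups
    )


def significance_threshold(spec: NutrientSpec, beverage: bool) -> float:
    """Cutoff amount per 100 mL (beverage) or 100 g (otherwise), in spec units."""
    return (BEVERAGE_FRACTION if beverage else SOLID_FRACTION) * spec.dri


def is_significant(value: float, spec: NutrientSpec, beverage: bool) -> bool:
    """Inclusive at the cutoff: a value equal to the threshold is significant."""
    if value < 0:
        raise ValueError(f"declared value must be >= 0, got {value}")
    return value >= significance_threshold(spec, beverage)
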