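"""Seeded generator of branded-food-shaped synthetic corpora.

The real Dutch branded-food database is access-restricted, so test corpora
are generated: Dutch-style ingredient lists assembled from a small template
grammar, with fortificants written standalone or as one-word compounds,
additive-class contexts, generic "vitaminen en mineralen" wording, "bron
van"/"rijk aan" remarks, and the documented data pathologies (truncated
lists, typos inside search terms, 1000-fold value errors, missing or
mis-assigned food groups).

Every generated food carries ground truth twice over: the label a
legally-literate reader would assign (``truth``) and the label the decision
tree is expected to assign (``expected``).  The two differ *by design* for
the documented error modes — mineral-water calcium mentions, below-threshold
declared fortificants, mis-filed ineligible foods, and corrupted records —
so the generator is an exact oracle for the classifier, errors included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_NUTRIENTS,
    FORTIFIED,
    INELIGIBLE,
    NON_FORTIFIED,
    BrandedFoodRecord,
)
from .significance import BEVERAGE_FRACTION, SOLID_FRACTION

SCENARIOS = (
    "clean_fortified",
    "generic_fortified",
    "additive_decoy",
    "natural_decoy",
    "mineral_water_bait",
    "below_significance",
    "step7_fortified",
    "ineligible_plain",
    "ineligible_misfiled",
    "unclassified_group",
    "corrupt_truncated",
    "corrupt_typo",
    "corrupt_unit_error",
    "plain",
)

_DRI = {"calcium": 800.0, "folic_acid": 200.0, "vitamin_b12": 2.5, "zinc": 10.0}

_BASE_INGREDIENTS = [
    "water", "tarwebloem", "suiker", "plantaardige olie", "zout", "gist",
    "magere melk", "sojabonen", "havermout", "cacaopoeder", "natuurlijk aroma",
    "rijstmeel", "maïszetmeel", "palmolie", "erwteneiwit", "glucosestroop",
]

_SOLID_GROUPS = [
    "Bread", "Cereals and cereal products", "Meat replacers",
    "Snacks (sweet and savory)", "Oils and fats", "Composite meals",
]

# (rendering, needs_compound) per nutrient: standalone term, one-word
# compound, two-word mixture, prefixed compound
_FORTIFICANT_FORMS = {
    "calcium": ["calcium", "calciumcarbonaat", "tricalciumcitraat", "calciumlactaat"],
    "folic_acid": ["foliumzuur", "foliumzuur", "folaat", "foliumzuur"],
    "vitamin_b12": ["vitamine B12", "cyanocobalamine", "B12", "cobalamine"],
    "zinc": ["zink", "zinklactaat", "zink gluconaat", "zinkoxide"],
}

_ADDITIVE_RENDERINGS = {
    "calcium": [
        "stabilisator (calciumcarbonaat)",
        "verdikkingsmiddel (calciumalginaat)",
        "antioxidant: calciumlactaat",
        "zuurteregelaar calciumhydroxide",
    ],
    "zinc": [
        "conserveermiddel (zinkoxide)",
        "antioxidant: zinkgluconaat",
        "stabilisator zinklactaat",
    ],
}

_FOOD_NAMES = {
    "clean_fortified": "ontbijtgranen",
    "generic_fortified": "vitaminedrank",
    "additive_decoy": "dessert",
    "natural_decoy": "zuivelsnack",
    "mineral_water_bait": "mineraalwater",
    "below_significance": "vleesvervanger",
    "step7_fortified": "halvarine",
    "ineligible_plain": "zuigelingenvoeding",
    "ineligible_misfiled": "opvolgmelk",
    "unclassified_group": "koek",
    "corrupt_truncated": "mueslireep",
    "corrupt_typo": "sojadrink",
    "corrupt_unit_error": "yoghurt",
    "plain": "volkorenbrood",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """How many foods of each scenario family to generate, per nutrient.

    ``counts`` maps scenario name -> {nutrient -> count}; ``plain_count``
    adds foods with no fortification story at all, of which a
    ``missing_group_prob`` fraction loses its food-group assignment.
    """

    counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    plain_count: int = 0
    seed: int = 0
    nutrients: tuple[str, ...] = DEFAULT_NUTRIENTS
    beverage_fraction: float = 0.3
    missing_group_prob: float = 0.0  # applied to plain foods

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenario families: {sorted(unknown)}")
        for scenario, per_nutrient in self.counts.items():
            bad = set(per_nutrient) - set(self.nutrients)
            if bad:
                raise ValueError(f"{scenario}: nutrients not configured: {sorted(bad)}")
            if any(c < 0 for c in per_nutrient.values()):
                raise ValueError(f"{scenario}: negative count")
        if scenario_total(self) == 0:
            raise ValueError("empty scenario config")
        if not 0 <= self.missing_group_prob <= 1:
            raise ValueError("missing_group_prob must be a probability")


def scenario_total(config: ScenarioConfig) -> int:
    return (
        sum(c for per in config.counts.values() for c in per.values())
        + config.plain_count
    )


def _threshold(nutrient: str, beverage: bool) -> float:
    return (BEVERAGE_FRACTION if beverage else SOLID_FRACTION) * _DRI[nutrient]


class _Builder:
    """Accumulates one corpus plus its ground-truth bookkeeping."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.records: list[BrandedFoodRecord] = []
        self.truth_rows: list[dict] = []
        self._counter = 0

    def new_id(self) -> str:
        self._counter += 1
        return f"F{self._counter:06d}"

    def base_ingredients(self, k: int = 4) -> list[str]:
        idx = self.rng.choice(len(_BASE_INGREDIENTS), size=k, replace=False)
        return [_BASE_INGREDIENTS[i] for i in sorted(idx)]

    def pick_context(self) -> tuple[Optional[str], Optional[str], bool]:
        """(food_group, subgroup, beverage?) for an eligible food."""
        if self.rng.random() < self.config.beverage_fraction:
            if self.rng.random() < 0.5:
                return "Drinks", None, True
            return "Milk, milk products, and milk replacers", "dairy drinks", True
        group = _SOLID_GROUPS[self.rng.integers(len(_SOLID_GROUPS))]
        return group, None, False

    def add(
        self,
        record: BrandedFoodRecord,
        scenario: str,
        focal: Optional[str],
        truth_focal: str,
        expected_focal: str,
        compliant: bool,
        food_level_truth: Optional[str] = None,
        food_level_expected: Optional[str] = None,
    ) -> None:
        """Register a record with per-nutrient ground truth.

        Non-focal nutrients default to non_fortified/non_fortified unless a
        food-level label (ineligible) overrides them.
        """
        self.records.append(record)
        for nutrient in self.config.nutrients:
            if nutrient == focal:
                truth, expected = truth_focal, expected_focal
            else:
                truth = food_level_truth or NON_FORTIFIED
                expected = food_level_expected or NON_FORTIFIED
            self.truth_rows.append(
                {
                    "food_id": record.food_id,
                    "nutrient": nutrient,
                    "truth": truth,
                    "expected": expected,
                    "scenario": scenario,
                    "compliance": compliant,
                }
            )


def _value_column(nutrient: str) -> str:
    return nutrient


def generate(config: ScenarioConfig) -> tuple[list[BrandedFoodRecord], pd.DataFrame]:
    """Build a corpus and its ground truth, deterministically from the seed."""
    b = _Builder(config)
    for scenario in SCENARIOS:  # fixed order => reproducible ids
        per_nutrient = config.counts.get(scenario, {})
        for nutrient in config.nutrients:
            for _ in range(per_nutrient.get(nutrient, 0)):
                _SCENARIO_BUILDERS[scenario](b, nutrient)
    for _ in range(config.plain_count):
        _build_plain(b)
    truth = pd.DataFrame(
        b.truth_rows,
        columns=["food_id", "nutrient", "truth", "expected", "scenario", "compliance"],
    )
    return b.records, truth


def expected_confusion(config: ScenarioConfig) -> dict[str, pd.DataFrame]:
    """Per-nutrient 3x3 table (truth rows x expected-procedure columns) that
    the classifier must reproduce exactly on the generated corpus."""
    _, truth = generate(config)
    out = {}
    for nutrient, block in truth.groupby("nutrient"):
        table = pd.crosstab(block["truth"], block["expected"])
        table = table.reindex(
            index=[FORTIFIED, NON_FORTIFIED, INELIGIBLE],
            columns=[FORTIFIED, NON_FORTIFIED, INELIGIBLE],
            fill_value=0,
        )
        out[nutrient] = table
    return out


# --- scenario builders -----------------------------------------------------


def _build_clean_fortified(b: _Builder, nutrient: str) -> None:
    group, subgroup, beverage = b.pick_context()
    form = _FORTIFICANT_FORMS[nutrient][b.rng.integers(len(_FORTIFICANT_FORMS[nutrient]))]
    ingredients = b.base_ingredients()
    ingredients.insert(int(b.rng.integers(1, len(ingredients) + 1)), form)
    value = _threshold(nutrient, beverage) * b.rng.uniform(1.0, 2.0)
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["clean_fortified"],
            ingredient_list=", ".join(ingredients),
            nutrient_values={_value_column(nutrient): round(value, 3)},
        ),
        "clean_fortified", nutrient, FORTIFIED, FORTIFIED, True,
    )


def _build_generic_fortified(b: _Builder, nutrient: str) -> None:
    # >=3 added micronutrients declared only as generic wording
    group, subgroup, beverage = b.pick_context()
    generic = ["vitaminen en mineralen", "vitaminen", "mineralen"][b.rng.integers(3)]
    ingredients = b.base_ingredients() + [generic]
    value = _threshold(nutrient, beverage) * b.rng.uniform(1.0, 2.0)
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["generic_fortified"],
            ingredient_list=", ".join(ingredients),
            nutrient_values={_value_column(nutrient): round(value, 3)},
        ),
        "generic_fortified", nutrient, FORTIFIED, FORTIFIED, True,
    )


def _build_additive_decoy(b: _Builder, nutrient: str) -> None:
    if nutrient not in _ADDITIVE_RENDERINGS:
        raise ValueError(
            f"additive_decoy is defined for minerals used as additives "
            f"(calcium, zinc), not {nutrient}"
        )
    group, subgroup, beverage = b.pick_context()
    rendering = _ADDITIVE_RENDERINGS[nutrient][
        b.rng.integers(len(_ADDITIVE_RENDERINGS[nutrient]))
    ]
    ingredients = b.base_ingredients() + [rendering]
    values = {}
    if b.rng.random() < 0.5:  # additive with significant natural level
        values[_value_column(nutrient)] = round(
            _threshold(nutrient, beverage) * b.rng.uniform(1.0, 1.5), 3
        )
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["additive_decoy"],
            ingredient_list=", ".join(ingredients),
            nutrient_values=values,
        ),
        "additive_decoy", nutrient, NON_FORTIFIED, NON_FORTIFIED, True,
    )


def _build_natural_decoy(b: _Builder, nutrient: str) -> None:
    group, subgroup, beverage = b.pick_context()
    term = _FORTIFICANT_FORMS[nutrient][0]
    value = _threshold(nutrient, beverage) * b.rng.uniform(1.0, 1.6)
    if b.rng.random() < 0.5:
        # remark inside the ingredient list
        ingredients = b.base_ingredients() + [f"(rijk aan {term})"]
        record = BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["natural_decoy"],
            ingredient_list=", ".join(ingredients),
            nutrient_values={_value_column(nutrient): round(value, 3)},
        )
    else:
        # remark in the mandatory particulars, nothing in the ingredients
        record = BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["natural_decoy"],
            ingredient_list=", ".join(b.base_ingredients()),
            mandatory_particulars=f"bron van {term}",
            nutrient_values={_value_column(nutrient): round(value, 3)},
        )
    b.add(record, "natural_decoy", nutrient, NON_FORTIFIED, NON_FORTIFIED, True)


def _build_mineral_water_bait(b: _Builder, nutrient: str) -> None:
    """Natural mineral content written into the ingredient list: the
    documented calcium false-positive mode, reproduced on purpose."""
    if nutrient != "calcium":
        raise ValueError("mineral_water_bait is a calcium scenario")
    mg = round(60 * b.rng.uniform(1.0, 1.5), 1)
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group="Drinks",
            food_name=_FOOD_NAMES["mineral_water_bait"],
            ingredient_list=f"bronwater (calcium {mg} mg/l, magnesium 10 mg/l)",
            nutrient_values={"calcium": mg},
        ),
        "mineral_water_bait", "calcium", NON_FORTIFIED, FORTIFIED, False,
    )


def _build_below_significance(b: _Builder, nutrient: str) -> None:
    """Fortificant declared but the value sits below the cutoff (the meat
    substitute pattern): a reader calls it fortified, the rules do not."""
    group = "Meat replacers" if nutrient == "vitamin_b12" else b.pick_context()[0]
    beverage = group == "Drinks"
    form = _FORTIFICANT_FORMS[nutrient][b.rng.integers(len(_FORTIFICANT_FORMS[nutrient]))]
    ingredients = b.base_ingredients() + [form]
    value = _threshold(nutrient, beverage) * b.rng.uniform(0.3, 0.9)
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_name=_FOOD_NAMES["below_significance"],
            ingredient_list=", ".join(ingredients),
            nutrient_values={_value_column(nutrient): round(value, 3)},
        ),
        "below_significance", nutrient, FORTIFIED, NON_FORTIFIED, False,
    )


def _build_step7_fortified(b: _Builder, nutrient: str) -> None:
    group, subgroup, _ = b.pick_context()
    term = _FORTIFICANT_FORMS[nutrient][0]
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["step7_fortified"],
            ingredient_list=", ".join(b.base_ingredients()),
            legal_name=f"{_FOOD_NAMES['step7_fortified']} verrijkt met {term}",
            nutrient_values={},
        ),
        "step7_fortified", nutrient, FORTIFIED, FORTIFIED, True,
    )


def _build_ineligible_plain(b: _Builder, nutrient: str) -> None:
    form = _FORTIFICANT_FORMS[nutrient][1]
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group="Foods and formulae for infants and young children",
            food_name=_FOOD_NAMES["ineligible_plain"],
            ingredient_list=", ".join(b.base_ingredients() + [form]),
            nutrient_values={_value_column(nutrient): round(_DRI[nutrient] * 0.2, 3)},
        ),
        "ineligible_plain", nutrient, INELIGIBLE, INELIGIBLE, True,
        food_level_truth=INELIGIBLE, food_level_expected=INELIGIBLE,
    )


def _build_ineligible_misfiled(b: _Builder, nutrient: str) -> None:
    """Expert-ineligible food filed into an eligible group: the procedure
    follows the (wrong) classification and calls the focal nutrient
    fortified."""
    form = _FORTIFICANT_FORMS[nutrient][1]
    value = _threshold(nutrient, False) * b.rng.uniform(1.2, 2.0)
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group="Milk, milk products, and milk replacers",
            food_name=_FOOD_NAMES["ineligible_misfiled"],
            ingredient_list=", ".join(b.base_ingredients() + [form]),
            nutrient_values={_value_column(nutrient): round(value, 3)},
        ),
        "ineligible_misfiled", nutrient, INELIGIBLE, FORTIFIED, False,
        food_level_truth=INELIGIBLE, food_level_expected=NON_FORTIFIED,
    )


def _build_unclassified_group(b: _Builder, nutrient: str) -> None:
    """Eligible food missing its group assignment: procedure-ineligible."""
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=None,
            food_name=_FOOD_NAMES["unclassified_group"],
            ingredient_list=", ".join(b.base_ingredients()),
            nutrient_values={},
        ),
        "unclassified_group", nutrient, NON_FORTIFIED, INELIGIBLE, False,
        food_level_truth=NON_FORTIFIED, food_level_expected=INELIGIBLE,
    )


def _build_corrupt_truncated(b: _Builder, nutrient: str) -> None:
    """Fortified food whose ingredient list was cut off before the term."""
    group, subgroup, beverage = b.pick_context()
    ingredients = b.base_ingredients()[:2]
    truncated = ", ".join(ingredients)
    truncated = truncated[: max(4, len(truncated) - int(b.rng.integers(1, 6)))]
    value = _threshold(nutrient, beverage) * b.rng.uniform(1.0, 2.0)
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["corrupt_truncated"],
            ingredient_list=truncated,
            nutrient_values={_value_column(nutrient): round(value, 3)},
        ),
        "corrupt_truncated", nutrient, FORTIFIED, NON_FORTIFIED, False,
    )


def _typo(rng: np.random.Generator, word: str) -> str:
    """Swap or delete one character near the start of the word.

    Hitting the leading characters guarantees the compound's head no longer
    matches any search term (a typo deep in "calciumcarbonaat" would leave
    the "calcium" head intact and still be found).
    """
    if len(word) < 4:
        return word + "x"
    i = int(rng.integers(1, 4))
    if rng.random() < 0.5 and word[i] != word[i + 1]:
        return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    return word[:i] + word[i + 1 :]


def _build_corrupt_typo(b: _Builder, nutrient: str) -> None:
    group, subgroup, beverage = b.pick_context()
    form = _FORTIFICANT_FORMS[nutrient][1]
    ingredients = b.base_ingredients() + [_typo(b.rng, form)]
    value = _threshold(nutrient, beverage) * b.rng.uniform(1.0, 2.0)
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["corrupt_typo"],
            ingredient_list=", ".join(ingredients),
            nutrient_values={_value_column(nutrient): round(value, 3)},
        ),
        "corrupt_typo", nutrient, FORTIFIED, NON_FORTIFIED, False,
    )


def _build_corrupt_unit_error(b: _Builder, nutrient: str) -> None:
    """A 1000-fold decimal/unit error on a natural, insignificant level."""
    group, subgroup, beverage = b.pick_context()
    natural = _threshold(nutrient, beverage) * b.rng.uniform(0.01, 0.2)
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["corrupt_unit_error"],
            ingredient_list=", ".join(b.base_ingredients()),
            nutrient_values={_value_column(nutrient): round(natural * 1000, 3)},
        ),
        "corrupt_unit_error", nutrient, NON_FORTIFIED, NON_FORTIFIED, False,
    )


def _build_plain(b: _Builder) -> None:
    if b.rng.random() < b.config.missing_group_prob:
        _build_unclassified_group(b, b.config.nutrients[0])
        return
    group, subgroup, _ = b.pick_context()
    b.add(
        BrandedFoodRecord(
            food_id=b.new_id(),
            food_group=group,
            food_subgroup=subgroup,
            food_name=_FOOD_NAMES["plain"],
            ingredient_list=", ".join(b.base_ingredients()),
            nutrient_values={},
        ),
        "plain", None, NON_FORTIFIED, NON_FORTIFIED, True,
    )


_SCENARIO_BUILDERS = {
    "clean_fortified": _build_clean_fortified,
    "generic_fortified": _build_generic_fortified,
    "additive_decoy": _build_additive_decoy,
    "natural_decoy": _build_natural_decoy,
    "mineral_water_bait": _build_mineral_water_bait,
    "below_significance": _build_below_significance,
    "step7_fortified": _build_step7_fortified,
    "ineligible_plain": _build_ineligible_plain,
    "ineligible_misfiled": _build_ineligible_misfiled,
    "unclassified_group": _build_unclassified_group,
    "corrupt_truncated": _build_corrupt_truncated,
    "corrupt_typo": _build_corrupt_typo,
    "corrupt_unit_error": _build_corrupt_unit_error,
}


def validation_design(
    seed: int = 0,
    fortified_per_nutrient: int = 100,
    other_count: int = 100,
) -> ScenarioConfig:
    """A config shaped like the expert-validation sampling design: a
    fortified-enriched stratum per nutrient plus a stratum of other foods
    (non-fortified, decoys, ineligible, corrupted)."""
    n_clean = int(round(fortified_per_nutrient * 0.8))
    n_generic = int(round(fortified_per_nutrient * 0.1))
    n_step7 = fortified_per_nutrient - n_clean - n_generic
    per = {n: n_clean for n in DEFAULT_NUTRIENTS}
    counts: dict[str, dict[str, int]] = {
        "clean_fortified": per,
        "generic_fortified": {n: n_generic for n in DEFAULT_NUTRIENTS},
        "step7_fortified": {n: n_step7 for n in DEFAULT_NUTRIENTS},
        "additive_decoy": {"calcium": 4, "zinc": 3},
        "natural_decoy": {n: 2 for n in DEFAULT_NUTRIENTS},
        "mineral_water_bait": {"calcium": 5},
        "below_significance": {"vitamin_b12": 4, "folic_acid": 2},
        "ineligible_plain": {n: 1 for n in DEFAULT_NUTRIENTS},
        "ineligible_misfiled": {"calcium": 2, "vitamin_b12": 2},
        "unclassified_group": {n: 1 for n in DEFAULT_NUTRIENTS},
        "corrupt_truncated": {n: 1 for n in DEFAULT_NUTRIENTS},
        "corrupt_typo": {n: 1 for n in DEFAULT_NUTRIENTS},
        "corrupt_unit_error": {n: 1 for n in DEFAULT_NUTRIENTS},
    }
    listed = sum(c for per_n in counts.values() for c in per_n.values())
    strata_other = listed - 4 * fortified_per_nutrient
    return ScenarioConfig(
        counts=counts,
        plain_count=max(0, other_count - strata_other),
        seed=seed,
    )
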