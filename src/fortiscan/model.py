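"""Domain types shared by every stage of the fortification pipeline.

A *branded-food record* is one food as supplied by its producer: a food-group
classification, free-text label fields (ingredient list, legal name, mandatory
particulars — Dutch in the reference database), and declared nutrient values
per 100 g or 100 mL.  The classifier labels each (food, nutrient) pair as
``fortified``, ``non_fortified`` or ``ineligible`` and keeps the ordered trace
of decision-tree steps that produced the label.

Absent nutrient values are modelled as *absent*, never as zero: an explicit 0
is a present (insignificant) declaration and routes differently through the
decision tree than a missing one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

FORTIFIED = "fortified"
NON_FORTIFIED = "non_fortified"
INELIGIBLE = "ineligible"

#: Fixed label order used by contingency tables and reports.
LABELS = (FORTIFIED, NON_FORTIFIED, INELIGIBLE)

#: Nutrients configured by default.  ``dfe`` (dietary folate equivalents) is an
#: input column only; it collapses onto ``folic_acid`` (see
#: :func:`effective_nutrient_value`).
DEFAULT_NUTRIENTS = ("calcium", "folic_acid", "vitamin_b12", "zinc")


@dataclass(frozen=True)
class BrandedFoodRecord:
    """One food as provided by a producer.

    ``nutrient_values`` maps nutrient id → declared amount per 100 g/mL
    (calcium mg, folic_acid μg, dfe μg, vitamin_b12 μg, zinc mg).  Missing
    declarations are simply absent from the mapping.
    """

    food_id: str
    food_group: Optional[str] = None
    food_subgroup: Optional[str] = None
    food_name: str = ""
    ingredient_list: Optional[str] = None
    legal_name: Optional[str] = None
    mandatory_particulars: Optional[str] = None
    nutrient_values: Mapping[str, float] = field(default_factory=dict)
    single_portion: Optional[bool] = None  # carried, never used by the tree


@dataclass(frozen=True)
class NutrientSpec:
    """Per-nutrient constants and search lexicon.

    The significance thresholds derive exactly from the adult daily reference
    intake: 7.5 % of the DRI per 100 mL for beverages, 15 % per 100 g for
    everything else.
    """

    nutrient_id: str
    unit: str
    dri: float
    specific_terms: tuple[str, ...]
    exclusion_patterns: tuple[str, ...] = ()
    value_columns: tuple[str, ...] = ()  # input columns, in priority order

    def __post_init__(self) -> None:
        if self.dri <= 0 or not math.isfinite(self.dri):
            raise ValueError(f"DRI must be a positive finite number, got {self.dri}")
        if not self.specific_terms:
            raise ValueError(f"{self.nutrient_id}: specific_terms must be non-empty")

    @property
    def beverage_threshold(self) -> float:
        return 0.075 * self.dri

    @property
    def solid_threshold(self) -> float:
        return 0.15 * self.dri


@dataclass(frozen=True)
class AdditiveClass:
    """One legally defined functional ingredient class (e.g. stabiliser)."""

    name: str
    terms: tuple[str, ...]


@dataclass(frozen=True)
class Lexicon:
    """Everything the text-matching layer needs beyond per-nutrient terms."""

    generic_terms: tuple[str, ...]
    additive_classes: tuple[AdditiveClass, ...]
    natural_content_phrases: tuple[str, ...]
    fortification_phrases: tuple[str, ...]
    qualifier_terms: tuple[str, ...] = ()
    compound_prefixes: tuple[str, ...] = ("mono", "di", "tri", "tetra")
    context_window: int = 3

    @property
    def additive_class_terms(self) -> tuple[str, ...]:
        return tuple(t for cls in self.additive_classes for t in cls.terms)


@dataclass(frozen=True)
class ClassificationResult:
    """Final label for one (food, nutrient) pair plus its replayable trace.

    ``trace`` is the ordered list of ``(step_number, outcome)`` pairs actually
    visited; replaying it (see :func:`replay_trace`) reproduces ``label``.
    """

    food_id: str
    nutrient_id: str
    label: str
    trace: tuple[tuple[int, str], ...]
    reason: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


# Outcomes that terminate the tree, and the label each one implies.
_TERMINAL_OUTCOMES = {
    (1, "ineligible"): INELIGIBLE,
    (5, "generic_found"): FORTIFIED,
    (6, "fortificant"): FORTIFIED,
    (6, "natural_content"): NON_FORTIFIED,
    (7, "fortification_wording"): FORTIFIED,
    (7, "natural_wording"): NON_FORTIFIED,
    (7, "no_evidence"): NON_FORTIFIED,
}


def replay_trace(trace: Sequence[tuple[int, str]]) -> str:
    """Label implied by a step trace, independent of the classifier.

    Raises ``ValueError`` if the trace does not start at step 1, is not
    strictly increasing, or does not end in a terminal outcome.
    """
    if not trace:
        raise ValueError("empty trace")
    if trace[0][0] != 1:
        raise ValueError("trace must start at step 1")
    steps = [s for s, _ in trace]
    if any(b <= a for a, b in zip(steps, steps[1:])):
        raise ValueError("step numbers must strictly increase")
    last = (trace[-1][0], trace[-1][1])
    if last not in _TERMINAL_OUTCOMES:
        raise ValueError(f"trace ends in non-terminal outcome {last}")
    return _TERMINAL_OUTCOMES[last]


def effective_nutrient_value(
    record: BrandedFoodRecord, spec: NutrientSpec
) -> Optional[float]:
    """Declared value for a nutrient, or ``None`` when nothing is declared.

    For folic acid two input columns exist: dietary folate equivalents (DFE)
    and plain folic acid.  When DFE is present it wins, as the more complete
    indicator of folic-acid fortification; otherwise the folic-acid column is
    used.  Column priority is carried by ``spec.value_columns``.
    """
    columns = spec.value_columns or (spec.nutrient_id,)
    for col in columns:
        if col in record.nutrient_values:
            v = record.nutrient_values[col]
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                return float(v)
    return None


def validate_record(record: BrandedFoodRecord) -> list[str]:
    """Informational issue codes for a record; never raises.

    Degraded data is a modelled condition: classification proceeds regardless
    of what is reported here.
    """
    issues: list[str] = []
    for nutrient, value in record.nutrient_values.items():
        if value is None:
            continue
        if isinstance(value, float) and math.isnan(value):
            issues.append(f"nan_value:{nutrient}")
        elif not math.isfinite(value):
            issues.append(f"non_finite_value:{nutrient}")
        elif value < 0:
            issues.append("negative_value")
    if record.food_group is None or str(record.food_group).strip() == "":
        issues.append("unknown_food_group")
    if record.ingredient_list is None or str(record.ingredient_list).strip() == "":
        issues.append("missing_ingredient_list")
    return issues


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 expert-vs-procedure counts, rows and columns in ``LABELS`` order."""

    counts: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.counts) != 3 or any(len(r) != 3 for r in self.counts):
            raise ValueError("contingency table must be 3x3")
        if any(c < 0 for row in self.counts for c in row):
            raise ValueError("counts must be non-negative")

    def row(self, expert_label: str) -> tuple[int, int, int]:
        return self.counts[LABELS.index(expert_label)]

    def cell(self, expert_label: str, procedure_label: str) -> int:
        return self.counts[LABELS.index(expert_label)][LABELS.index(procedure_label)]

    @property
    def total(self) -> int:
        return sum(c for row in self.counts for c in row)


@dataclass(frozen=True)
class SimultaneousCI:
    """Simultaneous interval for one multinomial category."""

    category: int
    point: float
    lower: float
    upper: float
    confidence_level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError(
                f"interval ordering violated: {self.lower}, {self.point}, {self.upper}"
            )
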