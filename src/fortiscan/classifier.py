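"""The seven-step decision tree that labels each (food, nutrient) pair.

    1. Is the food eligible?                       no  -> ineligible
    2. Is a nutrient value declared?               no  -> step 7
    3. Is the declared value significant?          no  -> step 7
    4. Is the nutrient in the ingredient list?     no  -> step 5
    5. Generic vitamin/mineral wording present?    yes -> fortified
                                                   no  -> step 7
    6. Additive context only                       ->     step 7
       natural-content remark (no plain match)     ->     non-fortified
       otherwise                                   ->     fortified
    7. Term + "added"/"fortified" wording          ->     fortified
       term + "source of"/"rich in" wording        ->     non-fortified
       anything else                               ->     non-fortified

Every classification carries the ordered trace of steps visited, so any
result can be replayed and audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .config import EligibilityRule, ProcedureConfig
from .lexicon import TermMatch, find_generic_terms, find_specific_terms
from .model import (
    FORTIFIED,
    INELIGIBLE,
    NON_FORTIFIED,
    BrandedFoodRecord,
    ClassificationResult,
    NutrientSpec,
    effective_nutrient_value,
)
from .significance import is_beverage, is_significant

STEP_COLUMNS = [f"step{i}" for i in range(1, 8)]


def step1_eligible(record: BrandedFoodRecord, rule: EligibilityRule) -> str:
    """'eligible' or 'ineligible'; nutrient-independent."""
    group = record.food_group
    if group is None or str(group).strip() == "":
        return "ineligible" if rule.treat_unclassified_as_ineligible else "eligible"
    if group in rule.ineligible_groups:
        return "ineligible"
    return "eligible"


def step2_value_declared(record: BrandedFoodRecord, spec: NutrientSpec) -> bool:
    return effective_nutrient_value(record, spec) is not None


def step3_significant(
    record: BrandedFoodRecord, spec: NutrientSpec, config: ProcedureConfig
) -> bool:
    value = effective_nutrient_value(record, spec)
    if value is None:
        raise ValueError("step 3 requires a declared value")
    return is_significant(value, spec, is_beverage(record, config.beverage_rule))


def step4_matches(
    record: BrandedFoodRecord, spec: NutrientSpec, config: ProcedureConfig
) -> list[TermMatch]:
    """Specific-term matches in the ingredient list (absent list = no match)."""
    return find_specific_terms(record.ingredient_list or "", spec, config.lexicon)


def step5_generic(record: BrandedFoodRecord, config: ProcedureConfig) -> list[TermMatch]:
    return find_generic_terms(record.ingredient_list or "", config.lexicon, config.specs)


def step6_outcome(matches: Sequence[TermMatch]) -> str:
    """'additive_context' | 'natural_content' | 'fortificant'.

    A plain fortificant match (neither additive-governed nor inside a
    natural-content remark) always wins; only when every match is
    additive-governed does the food divert to step 7, and only a
    natural-content remark without any plain match reads as natural content.
    """
    if not matches:
        raise ValueError("step 6 requires at least one specific-term match")
    if all(m.in_additive_context for m in matches):
        return "additive_context"
    plain = [
        m
        for m in matches
        if not m.in_additive_context and not m.in_natural_content_remark
    ]
    if any(m.in_natural_content_remark for m in matches) and not plain:
        return "natural_content"
    return "fortificant"


def step7_outcome(
    record: BrandedFoodRecord, spec: NutrientSpec, config: ProcedureConfig
) -> str:
    """'fortification_wording' | 'natural_wording' | 'no_evidence'.

    Searches the legal name and mandatory particulars (and the food name only
    when configured) for specific or generic terms; a term co-occurring with
    "added"/"fortified" wording classifies fortified, with "source of"/"rich
    in" wording non-fortified.  Bare phrases without a term never classify.
    """
    fields = [record.legal_name, record.mandatory_particulars]
    if config.search_food_name:
        fields.append(record.food_name)
    saw_natural = False
    for text in fields:
        if not text:
            continue
        matches = list(find_specific_terms(text, spec, config.lexicon))
        matches += find_generic_terms(text, config.lexicon, config.specs)
        for m in matches:
            if m.in_fortification_remark:
                return "fortification_wording"
            if m.in_natural_content_remark:
                saw_natural = True
    return "natural_wording" if saw_natural else "no_evidence"


def classify_food(
    record: BrandedFoodRecord, config: ProcedureConfig
) -> list[ClassificationResult]:
    """Run the decision tree for every configured nutrient of one food."""
    results = []
    eligibility = step1_eligible(record, config.eligibility_rule)
    for spec in config.specs:
        results.append(_classify_one(record, spec, config, eligibility))
    return results


def _classify_one(
    record: BrandedFoodRecord,
    spec: NutrientSpec,
    config: ProcedureConfig,
    eligibility: str,
) -> ClassificationResult:
    trace: list[tuple[int, str]] = [(1, eligibility)]
    if eligibility == "ineligible":
        reason = (
            "step1_unclassified"
            if record.food_group is None or str(record.food_group).strip() == ""
            else "step1_ineligible_group"
        )
        return ClassificationResult(
            record.food_id, spec.nutrient_id, INELIGIBLE, tuple(trace), reason
        )

    declared = step2_value_declared(record, spec)
    trace.append((2, "declared" if declared else "missing"))
    if declared:
        significant = step3_significant(record, spec, config)
        trace.append((3, "significant" if significant else "not_significant"))
        if significant:
            matches = step4_matches(record, spec, config)
            trace.append((4, "term_found" if matches else "no_term"))
            if matches:
                outcome = step6_outcome(matches)
                trace.append((6, outcome))
                if outcome == "fortificant":
                    return ClassificationResult(
                        record.food_id, spec.nutrient_id, FORTIFIED, tuple(trace),
                        "step6_fortificant",
                    )
                if outcome == "natural_content":
                    return ClassificationResult(
                        record.food_id, spec.nutrient_id, NON_FORTIFIED, tuple(trace),
                        "step6_natural_remark",
                    )
                # additive context: fall through to step 7
            else:
                generic = step5_generic(record, config)
                trace.append((5, "generic_found" if generic else "no_generic"))
                if generic:
                    return ClassificationResult(
                        record.food_id, spec.nutrient_id, FORTIFIED, tuple(trace),
                        "step5_generic_fortified",
                    )

    outcome = step7_outcome(record, spec, config)
    trace.append((7, outcome))
    label = FORTIFIED if outcome == "fortification_wording" else NON_FORTIFIED
    reason = {
        "fortification_wording": "step7_fortification_wording",
        "natural_wording": "step7_natural_wording",
        "no_evidence": "step7_natural_default",
    }[outcome]
    return ClassificationResult(
        record.food_id, spec.nutrient_id, label, tuple(trace), reason
    )


@dataclass
class StepTally:
    """Per-nutrient yes/no counts for each decision-tree step.

    "yes" answers the step's question: eligible (1), value declared (2),
    significant (3), term in ingredients (4), generic wording found (5),
    additive-or-natural (6, the food is diverted), fortified wording found
    (7).
    """

    counts: dict[str, dict[int, dict[str, int]]] = field(default_factory=dict)

    def add(self, nutrient: str, step: int, yes: bool) -> None:
        steps = self.counts.setdefault(
            nutrient, {i: {"yes": 0, "no": 0} for i in range(1, 8)}
        )
        steps[step]["yes" if yes else "no"] += 1

    def yes(self, nutrient: str, step: int) -> int:
        return self.counts.get(nutrient, {}).get(step, {}).get("yes", 0)

    def fortified_from_steps(self, nutrient: str) -> int:
        """Fortified count reconstructed from the per-step yes counts.

        yes4 − yes6 gives the foods confirmed fortified at step 6; foods
        fortified on generic wording (step 5) and on label wording (step 7)
        complete the total.  With no step-5 classifications this reduces to
        the yes4 − yes6 + yes7 bookkeeping of the step report.
        """
        return (
            self.yes(nutrient, 4)
            - self.yes(nutrient, 6)
            + self.yes(nutrient, 5)
            + self.yes(nutrient, 7)
        )


_YES_OUTCOMES = {
    1: {"eligible"},
    2: {"declared"},
    3: {"significant"},
    4: {"term_found"},
    5: {"generic_found"},
    6: {"additive_context", "natural_content"},
    7: {"fortification_wording"},
}


def classify_dataset(
    records: Iterable[BrandedFoodRecord],
    config: ProcedureConfig,
    include_trace: bool = False,
) -> tuple[pd.DataFrame, StepTally]:
    """Classify every record for every configured nutrient.

    Returns a results table (one row per food x nutrient, with per-step
    outcome columns: ``y``/``n``/``-`` for not visited) and the per-step
    tally.
    """
    tally = StepTally()
    rows = []
    for record in records:
        for result in classify_food(record, config):
            visited = {step: outcome for step, outcome in result.trace}
            row = {
                "food_id": result.food_id,
                "nutrient": result.nutrient_id,
                "label": result.label,
                "terminal_step": result.trace[-1][0],
                "reason": result.reason,
            }
            for step in range(1, 8):
                if step in visited:
                    yes = visited[step] in _YES_OUTCOMES[step]
                    row[f"step{step}"] = "y" if yes else "n"
                    tally.add(result.nutrient_id, step, yes)
                else:
                    row[f"step{step}"] = "-"
            if include_trace:
                row["trace"] = ">".join(f"{s}:{o}" for s, o in result.trace)
            rows.append(row)
    columns = ["food_id", "nutrient", "label", "terminal_step", "reason", *STEP_COLUMNS]
    if include_trace:
        columns.append("trace")
    frame = pd.DataFrame(rows, columns=columns)
    return frame, tally
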