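"""Configuration loading: nutrient specs, lexicon, group rules.

The default configuration ships with the package; user configs are YAML files
of the same shape and may override any part.  Adding a nutrient to the
procedure is a pure config change.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from .model import AdditiveClass, Lexicon, NutrientSpec


@dataclass(frozen=True)
class BeverageRule:
    """Categorical beverage membership (no inference from food names)."""

    beverage_food_groups: frozenset[str]
    beverage_subgroups: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.beverage_food_groups & self.beverage_subgroups
        if overlap:
            raise ValueError(f"groups and subgroups overlap: {sorted(overlap)}")


@dataclass(frozen=True)
class EligibilityRule:
    ineligible_groups: frozenset[str]
    treat_unclassified_as_ineligible: bool = True
    eligible_groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.ineligible_groups & self.eligible_groups
        if overlap:
            raise ValueError(f"ineligible groups overlap eligible set: {sorted(overlap)}")


@dataclass(frozen=True)
class ProcedureConfig:
    """Everything the decision tree needs, bundled."""

    specs: tuple[NutrientSpec, ...]
    lexicon: Lexicon
    beverage_rule: BeverageRule
    eligibility_rule: EligibilityRule
    search_food_name: bool = False

    def spec(self, nutrient_id: str) -> NutrientSpec:
        for s in self.specs:
            if s.nutrient_id == nutrient_id:
                return s
        raise KeyError(f"nutrient {nutrient_id!r} not configured")

    @property
    def nutrient_ids(self) -> tuple[str, ...]:
        return tuple(s.nutrient_id for s in self.specs)

    def subset(self, nutrients: Sequence[str]) -> "ProcedureConfig":
        specs = tuple(self.spec(n) for n in nutrients)
        return ProcedureConfig(
            specs=specs,
            lexicon=self.lexicon,
            beverage_rule=self.beverage_rule,
            eligibility_rule=self.eligibility_rule,
            search_food_name=self.search_food_name,
        )


def _norm(term: str) -> str:
    return " ".join(str(term).lower().split())


def default_config_dict() -> dict:
    """The packaged default configuration as a plain dict."""
    text = resources.files("fortiscan.data").joinpath("default_config.yaml").read_text(
        encoding="utf-8"
    )
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(
    source: Union[None, str, Path, Mapping] = None,
    nutrients: Optional[Sequence[str]] = None,
) -> ProcedureConfig:
    """Build a :class:`ProcedureConfig`.

    ``source`` may be ``None`` (packaged defaults), a YAML path, or a mapping;
    a path or mapping is merged over the defaults, so partial configs are
    fine.  ``nutrients`` restricts the procedure to a subset of configured
    nutrients.
    """
    data = default_config_dict()
    if source is not None:
        if isinstance(source, Mapping):
            data = _deep_merge(data, source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                user = yaml.safe_load(fh) or {}
            data = _deep_merge(data, user)
    return config_from_dict(data, nutrients=nutrients)


def config_from_dict(
    data: Mapping, nutrients: Optional[Sequence[str]] = None
) -> ProcedureConfig:
    nut_cfg = data["nutrients"]
    wanted = list(nutrients) if nutrients is not None else list(nut_cfg)
    missing = [n for n in wanted if n not in nut_cfg]
    if missing:
        raise KeyError(f"nutrients not in config: {missing}")

    specs = []
    for nid in wanted:
        block = nut_cfg[nid]
        specs.append(
            NutrientSpec(
                nutrient_id=nid,
                unit=str(block["unit"]),
                dri=float(block["dri"]),
                specific_terms=tuple(_norm(t) for t in block["specific_terms"]),
                exclusion_patterns=tuple(
                    _norm(t) for t in block.get("exclusion_patterns", []) or []
                ),
                value_columns=tuple(block.get("value_columns", [nid]) or [nid]),
            )
        )

    lex_cfg = data["lexicon"]
    classes = tuple(
        AdditiveClass(name=str(c["name"]), terms=tuple(_norm(t) for t in c["terms"]))
        for c in lex_cfg["additive_classes"]
    )
    # specific terms of every configured nutrient always qualify a generic word
    all_specific = [t for n in nut_cfg.values() for t in n["specific_terms"]]
    qualifiers = tuple(
        dict.fromkeys(
            [_norm(t) for t in lex_cfg.get("qualifier_terms", [])]
            + [_norm(t) for t in all_specific]
        )
    )
    lexicon = Lexicon(
        generic_terms=tuple(_norm(t) for t in lex_cfg["generic_terms"]),
        additive_classes=classes,
        natural_content_phrases=tuple(
            _norm(t) for t in lex_cfg["natural_content_phrases"]
        ),
        fortification_phrases=tuple(_norm(t) for t in lex_cfg["fortification_phrases"]),
        qualifier_terms=qualifiers,
        compound_prefixes=tuple(lex_cfg.get("compound_prefixes", ["mono", "di", "tri", "tetra"])),
        context_window=int(lex_cfg.get("context_window", 3)),
    )

    bev_cfg = data["beverage_rule"]
    beverage_rule = BeverageRule(
        beverage_food_groups=frozenset(str(g) for g in bev_cfg["food_groups"]),
        beverage_subgroups=frozenset(str(g) for g in bev_cfg["subgroups"]),
    )

    elig_cfg = data["eligibility"]
    eligibility_rule = EligibilityRule(
        ineligible_groups=frozenset(str(g) for g in elig_cfg["ineligible_groups"]),
        treat_unclassified_as_ineligible=bool(
            elig_cfg.get("treat_unclassified_as_ineligible", True)
        ),
        eligible_groups=frozenset(str(g) for g in elig_cfg.get("food_groups", [])),
    )

    return ProcedureConfig(
        specs=tuple(specs),
        lexicon=lexicon,
        beverage_rule=beverage_rule,
        eligibility_rule=eligibility_rule,
        search_food_name=bool(data.get("classifier", {}).get("search_food_name", False)),
    )
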