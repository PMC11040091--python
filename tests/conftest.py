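from __future__ import annotations

import pytest

from fortiscan import load_config
from fortiscan.synthgen import DEFAULT_NUTRIENTS, ScenarioConfig


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def lexicon(config):
    return config.lexicon


@pytest.fixture(scope="session")
def specs(config):
    return {s.nutrient_id: s for s in config.specs}


def mixed_scenario_config(seed: int, scale: int = 1, plain: int = 0) -> ScenarioConfig:
    """A corpus exercising every scenario family, ``scale`` foods per cell."""
    n = DEFAULT_NUTRIENTS
    return ScenarioConfig(
        counts={
            "clean_fortified": {k: 8 * scale for k in n},
            "generic_fortified": {k: 2 * scale for k in n},
            "additive_decoy": {"calcium": 3 * scale, "zinc": 3 * scale},
            "natural_decoy": {k: 2 * scale for k in n},
            "mineral_water_bait": {"calcium": 2 * scale},
            "below_significance": {k: 2 * scale for k in n},
            "step7_fortified": {k: 2 * scale for k in n},
            "ineligible_plain": {k: scale for k in n},
            "ineligible_misfiled": {k: scale for k in n},
            "unclassified_group": {k: scale for k in n},
            "corrupt_truncated": {k: scale for k in n},
            "corrupt_typo": {k: scale for k in n},
            "corrupt_unit_error": {k: scale for k in n},
        },
        plain_count=plain,
        seed=seed,
    )
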