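import dataclasses

from fortiscan import classify_dataset, classify_food, replay_trace
from fortiscan.classifier import step1_eligible, step6_outcome
from fortiscan.lexicon import TermMatch
from fortiscan.model import FORTIFIED, INELIGIBLE, NON_FORTIFIED, BrandedFoodRecord
from fortiscan.synthgen import generate

from conftest import mixed_scenario_config


def labels_for(record, config):
    return {r.nutrient_id: r.label for r in classify_food(record, config)}


class TestStep1:
    def test_ineligible_group(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Foods and formulae for infants and young children"
        )
        assert step1_eligible(r, config.eligibility_rule) == "ineligible"

    def test_unclassified_food(self, config):
        r = BrandedFoodRecord(food_id="x", food_group=None)
        assert step1_eligible(r, config.eligibility_rule) == "ineligible"

    def test_regular_group(self, config):
        r = BrandedFoodRecord(food_id="x", food_group="Cereals and cereal products")
        assert step1_eligible(r, config.eligibility_rule) == "eligible"

    def test_ineligibility_short_circuits_all_nutrients(self, config):
        r = BrandedFoodRecord(
            food_id="x",
            food_group="Foods and formulae for infants and young children",
            ingredient_list="melk, calciumcarbonaat, cyanocobalamine, zinkoxide, foliumzuur",
            nutrient_values={"calcium": 500, "vitamin_b12": 2, "zinc": 5, "folic_acid": 100},
        )
        assert set(labels_for(r, config).values()) == {INELIGIBLE}
        for result in classify_food(r, config):
            assert result.trace == ((1, "ineligible"),)


class TestRouting:
    def test_missing_value_goes_to_step7(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread", ingredient_list="tarwebloem, cyanocobalamine"
        )
        (result,) = [c for c in classify_food(r, config) if c.nutrient_id == "vitamin_b12"]
        assert result.trace[1] == (2, "missing")
        assert result.trace[-1][0] == 7

    def test_explicit_zero_routes_through_step3(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread", ingredient_list="tarwebloem",
            nutrient_values={"vitamin_b12": 0.0},
        )
        (result,) = [c for c in classify_food(r, config) if c.nutrient_id == "vitamin_b12"]
        assert result.trace[1] == (2, "declared")
        assert result.trace[2] == (3, "not_significant")

    def test_dfe_declares_folic_acid(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread", ingredient_list="tarwebloem, foliumzuur",
            nutrient_values={"dfe": 51.0},
        )
        (result,) = [c for c in classify_food(r, config) if c.nutrient_id == "folic_acid"]
        assert result.label == FORTIFIED  # 51 >= 30 via the DFE column

    def test_insignificant_beverage_cutoff_for_solid(self, config):
        # 60 mg calcium is the beverage cutoff; a solid food needs 120
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread", ingredient_list="tarwebloem, calciumcarbonaat",
            nutrient_values={"calcium": 60.0},
        )
        assert labels_for(r, config)["calcium"] == NON_FORTIFIED

    def test_significant_term_fortified(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread", ingredient_list="tarwebloem, calciumcarbonaat",
            nutrient_values={"calcium": 130.0},
        )
        assert labels_for(r, config)["calcium"] == FORTIFIED

    def test_absent_ingredient_list_is_no_match(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread", nutrient_values={"calcium": 130.0}
        )
        (result,) = [c for c in classify_food(r, config) if c.nutrient_id == "calcium"]
        assert result.trace[3] == (4, "no_term")
        assert result.label == NON_FORTIFIED

    def test_generic_wording_fortifies_significant_value(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Drinks",
            ingredient_list="water, suiker, vitaminen en mineralen",
            nutrient_values={"vitamin_b12": 0.5},
        )
        (result,) = [c for c in classify_food(r, config) if c.nutrient_id == "vitamin_b12"]
        assert result.label == FORTIFIED
        assert result.reason == "step5_generic_fortified"

    def test_qualified_generic_does_not_fortify(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Drinks", ingredient_list="water, vitamine C",
            nutrient_values={"calcium": 80.0},
        )
        assert labels_for(r, config)["calcium"] == NON_FORTIFIED


class TestStep6:
    def match(self, **flags):
        return TermMatch(term="calcium", span=(0, 7), token_indices=(0,), **flags)

    def test_all_additive_diverts(self):
        assert step6_outcome([self.match(in_additive_context=True)]) == "additive_context"

    def test_natural_remark_only_is_non_fortified(self):
        assert step6_outcome([self.match(in_natural_content_remark=True)]) == "natural_content"

    def test_plain_match_wins_over_additive_and_natural(self):
        matches = [
            self.match(in_additive_context=True),
            self.match(in_natural_content_remark=True),
            self.match(),
        ]
        assert step6_outcome(matches) == "fortificant"

    def test_additive_food_falls_through_to_step7(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread",
            ingredient_list="tarwebloem, stabilisator (calciumcarbonaat)",
            nutrient_values={"calcium": 150.0},
        )
        (result,) = [c for c in classify_food(r, config) if c.nutrient_id == "calcium"]
        assert (6, "additive_context") in result.trace
        assert result.label == NON_FORTIFIED

    def test_rich_in_remark_is_non_fortified(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread",
            ingredient_list="melkpoeder (rijk aan calcium)",
            nutrient_values={"calcium": 150.0},
        )
        assert labels_for(r, config)["calcium"] == NON_FORTIFIED


class TestStep7:
    def test_fortified_wording_in_legal_name(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Oils and fats",
            legal_name="halvarine verrijkt met foliumzuur",
        )
        assert labels_for(r, config)["folic_acid"] == FORTIFIED

    def test_source_of_wording_is_non_fortified(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread",
            mandatory_particulars="bron van calcium",
            nutrient_values={"calcium": 150.0},
        )
        assert labels_for(r, config)["calcium"] == NON_FORTIFIED

    def test_significant_value_without_any_terms_is_natural(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Cheese and cheese substitutes",
            ingredient_list="melk, zout, stremsel",
            nutrient_values={"calcium": 800.0},
        )
        (result,) = [c for c in classify_food(r, config) if c.nutrient_id == "calcium"]
        assert result.label == NON_FORTIFIED
        assert result.reason == "step7_natural_default"

    def test_bare_phrase_without_term_never_fortifies(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Bread", legal_name="brood verrijkt met vezels"
        )
        assert labels_for(r, config)["calcium"] == NON_FORTIFIED

    def test_food_name_ignored_by_default(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Drinks", food_name="drank verrijkt met calcium"
        )
        assert labels_for(r, config)["calcium"] == NON_FORTIFIED

    def test_food_name_searched_when_configured(self):
        from fortiscan import load_config

        cfg = load_config({"classifier": {"search_food_name": True}})
        r = BrandedFoodRecord(
            food_id="x", food_group="Drinks", food_name="drank verrijkt met calcium"
        )
        assert labels_for(r, cfg)["calcium"] == FORTIFIED


class TestDocumentedErrorModes:
    def test_mineral_water_false_positive_reproduced(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Drinks", food_name="mineraalwater",
            ingredient_list="bronwater (calcium 80 mg/l, magnesium 10 mg/l)",
            nutrient_values={"calcium": 80.0},
        )
        assert labels_for(r, config)["calcium"] == FORTIFIED

    def test_below_significance_fortificant_is_non_fortified(self, config):
        r = BrandedFoodRecord(
            food_id="x", food_group="Meat replacers",
            ingredient_list="soja, cyanocobalamine",
            nutrient_values={"vitamin_b12": 0.2},
        )
        assert labels_for(r, config)["vitamin_b12"] == NON_FORTIFIED


class TestDatasetInvariants:
    def test_empty_dataset(self, config):
        frame, tally = classify_dataset([], config)
        assert frame.empty
        assert tally.counts == {}

    def test_partition_and_replay_on_mixed_corpus(self, config):
        records, _ = generate(mixed_scenario_config(seed=5, plain=40))
        frame, _ = classify_dataset(records, config)
        for nutrient in config.nutrient_ids:
            block = frame[frame["nutrient"] == nutrient]
            assert len(block) == len(records)
            assert block["label"].isin([FORTIFIED, NON_FORTIFIED, INELIGIBLE]).all()
        for result in (res for rec in records for res in classify_food(rec, config)):
            assert replay_trace(result.trace) == result.label
            assert (result.label == INELIGIBLE) == (result.trace[-1][0] == 1)

    def test_value_monotonicity_on_corpus(self, config):
        records, _ = generate(mixed_scenario_config(seed=11, plain=20))
        base = {
            (res.food_id, res.nutrient_id): res.label
            for rec in records
            for res in classify_food(rec, config)
        }
        for factor in (1.5, 10.0):
            for rec in records:
                if not rec.nutrient_values:
                    continue
                scaled = dataclasses.replace(
                    rec,
                    nutrient_values={k: v * factor for k, v in rec.nutrient_values.items()},
                )
                for res in classify_food(scaled, config):
                    if base[(rec.food_id, res.nutrient_id)] == FORTIFIED:
                        assert res.label == FORTIFIED

    def test_step_tally_identity(self, config):
        records, _ = generate(mixed_scenario_config(seed=3, plain=25))
        frame, tally = classify_dataset(records, config)
        for nutrient in config.nutrient_ids:
            fortified = int(
                ((frame["nutrient"] == nutrient) & (frame["label"] == FORTIFIED)).sum()
            )
            assert tally.fortified_from_steps(nutrient) == fortified
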