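# fortiscan

Rule-based identification of micronutrient-fortified foods in branded-food
label data.

## The problem

EU labeling legislation (Regulation 1169/2011) requires that added vitamins
and minerals appear in a food's ingredient list and that the total nutrient
content be declared when it is *significant* — at least 7.5 % of the adult
daily reference intake (DRI) per 100 mL for beverages, or 15 % per 100 g for
other foods. National branded-food databases hold label data for hundreds of
thousands of products but rarely flag fortification explicitly. fortiscan
encodes the labeling rules as a seven-step decision tree over the label
fields, so that fortified foods can be found automatically instead of food
by food — useful for intake modelling, monitoring of fortification
practice, and enforcement work.

Each (food, nutrient) pair is routed to one of three labels:

| step | question | route |
|------|----------|-------|
| 1 | Is the food eligible (general labeling rules apply)? | no → **ineligible** |
| 2 | Is a nutrient value declared? | no → step 7 |
| 3 | Is the declared value ≥ the significance cutoff? | no → step 7 |
| 4 | Is a nutrient search term in the ingredient list? | no → step 5 |
| 5 | Generic "vitamin(s)/mineral(s)" wording present? | yes → **fortified**, no → step 7 |
| 6 | Term governed by a food-additive class → step 7; "rich in / source of" remark → **non-fortified**; otherwise → **fortified** | |
| 7 | Term + "added/fortified with" wording → **fortified**; term + "source of / rich in" → **non-fortified**; else → **non-fortified** | |

The significance cutoffs derive exactly from the DRI: calcium 60/120 mg,
folic acid 15/30 μg, vitamin B12 0.1875/0.3750 μg, zinc 0.75/1.50 mg
(beverage / non-beverage, per 100 mL / 100 g). Matching handles the Dutch
habit of writing fortificant mixtures as single compound words
("zinklactaat", "tricalciumcitraat") and the exclusions and qualifier rules
that keep "calcium-D-pantothenaat" and "vitamine C" from counting.

For validation the package builds 3×3 expert-vs-procedure contingency
tables, sensitivity/specificity, and Sison–Glaz simultaneous confidence
intervals for multinomial proportions: with counts *n₁…n_k*, find the
half-width *c* with ν(c) < 1−α ≤ ν(c+1) (ν approximated by truncated-Poisson
products with a second-order Edgeworth correction) and report
[p̂ᵢ − c/n, p̂ᵢ + c/n + 2γ/n].

Because the underlying branded-food database is access-restricted, the
package ships a seeded generator of database-shaped corpora with exact
per-record ground truth, including the documented error modes (mineral-water
calcium mentions, below-threshold declared fortificants, truncated
ingredient lists, typos, 1000-fold value errors, mis-filed food groups).

## Worked example

```python
from fortiscan import FortificationClassifier, BrandedFoodRecord

clf = FortificationClassifier().fit()
foods = [
    BrandedFoodRecord(
        food_id="muesli-01", food_group="Cereals and cereal products",
        ingredient_list="havermout, rozijnen, calciumcarbonaat, foliumzuur",
        nutrient_values={"calcium": 240.0, "folic_acid": 51.0}),
    BrandedFoodRecord(
        food_id="water-01", food_group="Drinks", food_name="mineraalwater",
        ingredient_list="bronwater (calcium 80 mg/l)",
        nutrient_values={"calcium": 80.0}),
    BrandedFoodRecord(
        food_id="toetje-07", food_group="Milk, milk products, and milk replacers",
        ingredient_list="melk, suiker, stabilisator (calciumalginaat)",
        nutrient_values={"calcium": 150.0}),
]
print(clf.predict(foods))
```

```
[['fortified' 'fortified' 'non_fortified' 'non_fortified']
 ['fortified' 'non_fortified' 'non_fortified' 'non_fortified']
 ['non_fortified' 'non_fortified' 'non_fortified' 'non_fortified']]
```

Columns are (calcium, folic_acid, vitamin_b12, zinc). The muesli is
fortified with calcium (240 mg ≥ 120) and folic acid (51 μg ≥ 30). The
mineral water is *labelled* fortified: 80 mg/100 mL exceeds the 60 mg
beverage cutoff and "calcium" appears in the ingredient list — the
documented false-positive mode for naturally mineral-rich water. The
dessert is not fortified: its calcium arrives inside a stabiliser
(food-additive context), so despite the significant value it falls through
to step 7 and ends non-fortified. `clf.transform(foods)` returns the full
audit table:

```
  food_id         label  terminal_step                reason
muesli-01     fortified              6     step6_fortificant
 water-01     fortified              6     step6_fortificant
toetje-07 non_fortified              7 step7_natural_default
```

The same pipeline runs from the shell:

```bash
fortiscan simulate --seed 5 --out-dir demo          # synthetic 500-food corpus
fortiscan classify --input demo/dataset.csv --output demo/results.csv
fortiscan validate --pred demo/results.csv --truth demo/ground_truth.csv \
                   --alpha 0.05 --report demo/report.csv
```

which ends with per-nutrient agreement statistics such as

```
INFO fortiscan: calcium: sensitivity=0.980 specificity=0.977
INFO fortiscan: folic_acid: sensitivity=0.962 specificity=0.990
```

and a report CSV whose rows read like
`calcium,fortified,102,100 (98.0%) CI: 96.1-100.0%,…` — one row per expert
class with simultaneous confidence intervals per procedure class.

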