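# Methods

## Classification model

fortiscan labels every (food, nutrient) pair `fortified`, `non_fortified`
or `ineligible` by a fixed decision tree that operationalizes the EU
labeling rules (Regulation 1169/2011, with Regulation 1925/2006 defining
the scope). Nothing is learned from data: the procedure is deterministic,
auditable, and configurable. The estimator facade
(`FortificationClassifier`) therefore has a `fit` that only validates the
configuration and freezes it into fitted attributes.

Assumptions inherited from the legal framing:

* **Declared values are taken at face value**, per 100 g or 100 mL of the
  food as sold. No outlier correction, per-portion rescaling or
  prepared-state modelling is attempted.
* **An absent nutrient value is not a zero.** EU rules only require
  declaration of significant amounts, so absence routes to the label-text
  fallback (step 7), whereas an explicit 0 is an insignificant declared
  value (step 3 → step 7 with a different trace).
* **Fortification, restoration and substitution are indistinguishable** on
  a label; all are reported as `fortified`.
* **Eligibility is food-level**: infant foods, medical foods, total diet
  replacement and supplements answer to other legislation and
  short-circuit every nutrient at step 1, as do foods with no food-group
  assignment.
* **Beverage status is purely categorical** (a configured set of food
  groups and subgroups). Names are never parsed for "drink"-ness; a
  mis-grouped beverage is deliberately followed into the wrong threshold,
  because deterministic behavior given the classification is the contract.
* For folic acid, a declared dietary-folate-equivalents (DFE) value is
  used as the indicator of folic-acid fortification; when both DFE and a
  plain folic-acid value are present, DFE wins as the more complete
  quantity.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| DRI: calcium / folic acid / B12 / zinc | 800 / 200 / 2.5 / 10 | mg, μg, μg, mg | adult reference intakes used by the labeling rules |
| beverage cutoff | 7.5 % of DRI | per 100 mL | legislated significance fraction |
| solid cutoff | 15 % of DRI | per 100 g | legislated significance fraction; single-portion packs are not distinguished |
| cutoff comparison | inclusive (≥) | — | the legislation does not demand strictly greater |
| context window | 3 tokens | — | proximity for additive-class and remark detection; the legal texts specify no distance, so this is a configurable design constant |
| compound prefixes | mono, di, tri, tetra | — | "tricalciumcitraat" must match like "dicalciumfosfaat" |
| `search_food_name` | off | — | step 7 searches legal name and mandatory particulars; the food name is opt-in |

All of these live in `src/fortiscan/data/default_config.yaml`; adding a
nutrient is a config block (unit, DRI, search terms, optional exclusions),
no code.

## Text matching

Tokenization splits on commas, semicolons, colons, brackets, slashes and
whitespace; hyphens and periods stay inside tokens (needed for the
`calcium-D-pantothenaat` exclusion and for `vit.B12`-style spellings).
Matching is case- and diacritics-insensitive; normalization is
length-preserving so match spans always index the original text. A nutrient
term matches as a standalone token or as the leading component of a longer
compound token, optionally behind a multiplicity prefix. `B9/B11/B12` also
match glued to "vitamine" with an optional hyphen; bracketed misspellings
like `B(1)(2)` do not match — the tokenizer splits them apart — matching
the source database's documented data errors rather than repairing them.
Overlapping hits collapse onto the longest term, so `zinklactaat` is one
match, not two.

Additive context holds when a functional-ingredient-class name (24 legal
classes, matched by their Dutch names) opens the bracket or colon group the
match sits in, or stands within the context window before the match with no
comma/semicolon in between. Natural-content ("bron van", "rijk aan") and
fortification ("verrijkt met", "toegevoegd") remarks are detected in the
same window. Generic wordings ("vitaminen en mineralen" and variants) count
only when not immediately qualified by a specific micronutrient name; the
qualifier vocabulary ships in the config and always includes the configured
nutrients' own terms.

No fuzzy or edit-distance matching is attempted: typos in ingredient lists
cause misses by design, and the synthetic generator reproduces exactly that
behavior.

## Validation statistics

Expert-vs-procedure comparisons are 3×3 contingency tables in the fixed
order (fortified, non-fortified, ineligible). Sensitivity is
TP / (TP + FN) over the procedure's fortified/non-fortified calls —
procedure-ineligible foods are excluded from the denominator — while
specificity is TN over the full expert-non-fortified row including
procedure-ineligible foods. This asymmetry is the convention that
back-calculates the published validation table; both denominators are
switchable.

Sison–Glaz simultaneous intervals: for counts *n₁…n_k* with total *n*, the
coverage proxy ν(c) multiplies doubly-truncated-Poisson cell masses with an
Edgeworth-corrected density for the conditioning event, using the
second-order polynomial 1 + γ₁(z³−3z)/6 + γ₂(z⁴−6z²+3)/24. The sixth-order
γ₁² term that some implementations add is deliberately omitted: the
second-order form is what reproduces the published interval bounds this
package is checked against. The search walks c upward from 1 with the
previous ν initialized to 0, takes the first c with ν > 1−α, interpolates
γ = (1−α−ν(c−1))/(ν(c)−ν(c−1)), and reports half-width (c−1)/n plus the
2γ/n upper correction, truncated to [0, 1]. Degenerate rows (one nonzero
cell) resolve on the first step and give valid zero-width intervals.

Two numerical caveats, measured against exact multinomial enumeration in
the test suite: the approximation is good (≤ 0.05 absolute) when every cell
count is ≥ 2, but overshoots (can exceed 1) for very skewed small-n vectors
like (28, 1, 1), worst observed deviation 0.08. And the construction itself
runs liberal for few categories: at n = 100, k = 3, p = (0.8, 0.15, 0.05)
the true simultaneous coverage measures ≈ 0.92 at nominal 0.95 — with the
exact-enumeration ν as well — so this is a property of the method, not of
the approximation.

Report percentages round half-away-from-zero to one decimal.

## Synthetic corpora

The generator emulates the structure of a Dutch branded-food database
export: per-food free-text label fields assembled from a small Dutch
template grammar (base ingredients, additive groups, vitamin/mineral
tails), food groups and beverage subgroups, and per-nutrient declared
values. Scenario families cover every branch of the tree: clean fortified
(declared value drawn uniformly between 1.0× and 2.0× the applicable
cutoff, fortificant rendered standalone, compound, two-word or prefixed),
generic-wording fortified, additive-context decoys (calcium/zinc inside
stabiliser/antioxidant/thickener groups), "rijk aan / bron van" natural
decoys, mineral-water calcium baits, below-cutoff declared fortificants
(0.3–0.9× the cutoff), label-wording-only fortification, properly filed
and mis-filed ineligible foods, unclassified foods, and corrupted records
(ingredient lists truncated mid-token, one-character typos near the head of
a search term, 1000-fold value errors).

Every food carries two ground-truth labels per nutrient: what a
legally-literate reader would conclude, and what the decision tree should
output. They differ by construction for the error-mode families, which
makes the generator an exact oracle: the test suite asserts cell-for-cell
equality between the classifier's confusion table and the generator's
bookkeeping on 10,300-food corpora, plus agreement with an independently
coded nested-conditional re-implementation of the tree. Generation is
deterministic: one seed, byte-identical CSV.

What passing these tests does *not* show: performance on real label text
beyond the template grammar (free word order, nested brackets three deep,
marketing copy), real prevalence (the generator's scenario mix is a test
design, not a market model), or robustness to wording variants absent from
the lexicon. The published validation against human experts is the evidence
for real-data behavior; the synthetic suite shows the implementation is
faithful to the specified procedure.

## Design choices where the procedure was open

* **Step 6 tie-break**: a food with both an additive-governed match and a
  plain fortificant match is fortified — the plain mention is independent
  evidence of addition.
* **Step 7 scope**: legal name and mandatory particulars only; bare
  "verrijkt met" without any nutrient term never classifies (phrase-only
  matching is known to flood the results with out-of-scope nutrients).
  Generic wordings are accepted in step 7 on the same qualifier rules as
  step 5.
* **Step-count bookkeeping**: the fortified total per nutrient equals
  yes₄ − yes₆ + yes₅ + yes₇ on any corpus (yes₆ counting foods diverted at
  step 6); without step-5 classifications this reduces to the shorter
  yes₄ − yes₆ + yes₇ identity used in step-count reporting.
* **Missing text fields** are empty strings at steps 4–7; missing values
  and groups are modelled conditions, never errors.
* Problem sizes in the test suite (10,300-food corpora, 5,000 Monte-Carlo
  replicates) were chosen to exercise every scenario family with stable
  statistics while keeping the default test run fast.

## Known limitations

* Maximum-fortification-level and legal-exemption checking is out of scope.
* Amounts added, chemical form and bioavailability are not estimated.
* Single-portion packages are not distinguished from other non-beverages;
  whether single-portion beverages take the 7.5 % or 15 % cutoff is legally
  unclear and left unresolved.
* The generic-wording step can only be exact once every addable
  micronutrient is configured; with a subset, generic matches may refer to
  out-of-scope nutrients.
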