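# Default fortiscan configuration.
#
# Nutrient blocks carry the adult daily reference intake (DRI) used by the EU
# labeling legislation to scale significance thresholds (7.5% of DRI per
# 100 mL for beverages, 15% per 100 g otherwise) and the Dutch search terms
# used to detect the nutrient inside ingredient lists.  Adding a nutrient to
# the procedure means adding a block here.

nutrients:
  calcium:
    unit: mg
    dri: 800
    value_columns: [calcium]
    specific_terms:
      - calcium
      - calciumcarbonaat
      - calciumfosfaat
      - dicalciumfosfaat
      - calciumlactaat
      - tricalciumcitraat
      - calciumcitraat
      - calciumzouten van orthofosforzuur
      - dicalciumdicitraat
      - calciumhydroxide
    # calcium-D-pantothenate is pantothenic acid, not calcium fortification
    exclusion_patterns:
      - calcium-d-pantothenaat
      - calcium-d-pantothenate
      - calciumpantothenaat
  folic_acid:
    unit: ug
    dri: 200
    # dietary folate equivalents, when declared, indicate folic-acid
    # fortification and take priority over the plain folic-acid column
    value_columns: [dfe, folic_acid]
    specific_terms:
      - foliumzuur
      - b9
      - b11
      - folaat
      - tetrahydrofolaat
      - polyglytamaat
      - pfteroylmonoglutaminezuur
      - folic acid
      - folinezuur
      - foliumzout
    exclusion_patterns: []
  vitamin_b12:
    unit: ug
    dri: 2.5
    value_columns: [vitamin_b12]
    specific_terms:
      - b12
      - cobalamine
      - cyanocobalamine
    exclusion_patterns: []
  zinc:
    unit: mg
    dri: 10
    value_columns: [zinc]
    specific_terms:
      - zink
      - zinklactaat
      - zink lactaat
      - zinksulfaat
      - zink sulfaat
      - zinkoxide
      - zink oxide
      - zinkgluconaat
      - zink gluconaat
      - zinkcitraat
      - zink citraat
    exclusion_patterns: []

lexicon:
  # Generic wordings allowed on EU labels when three or more micronutrients
  # are added.  A generic word immediately qualified by a specific
  # micronutrient name ("vitamine C") is not a generic match.
  generic_terms:
    - vitamine
    - vitaminen
    - vitamines
    - mineralen
    - mineraal
    - vitamines en mineralen
    - vitaminen en mineralen
    - vitamine en mineralen
  # The 24 legally defined functional ingredient classes.  A nutrient name
  # governed by one of these in an ingredient list is a food additive, not a
  # fortificant.  Canonical names in English; match terms are the Dutch class
  # names as they appear on labels.
  additive_classes:
    - name: Acid
      terms: [voedingszuur, zuur, acid]
    - name: Acidity regulator
      terms: [zuurteregelaar, zuurteregelaars, acidity regulator]
    - name: Anti-caking agent
      terms: [antiklontermiddel, anti-klontermiddel, anticaking agent]
    - name: Anti-foaming agent
      terms: [antischuimmiddel, anti-schuimmiddel]
    - name: Antioxidant
      terms: [antioxidant, antioxidanten, anti-oxidant]
    - name: Bulking agent
      terms: [vulstof, vulstoffen]
    - name: Color
      terms: [kleurstof, kleurstoffen, kleur]
    - name: Emulsifier
      terms: [emulgator, emulgatoren]
    - name: Emulsifying salts
      terms: [smeltzout, smeltzouten]
    - name: Firming agent
      terms: [verstevigingsmiddel, verstevigingsmiddelen]
    - name: Flavor enhancer
      terms: [smaakversterker, smaakversterkers]
    - name: Flour treatment agent
      terms: [meelverbeteraar, meelverbeteraars]
    - name: Foaming agent
      terms: [schuimmiddel, schuimmiddelen]
    - name: Gelling agent
      terms: [geleermiddel, geleermiddelen]
    - name: Glazing agent
      terms: [glansmiddel, glansmiddelen]
    - name: Humectant
      terms: [bevochtigingsmiddel, bevochtigingsmiddelen]
    - name: Modified starch
      terms: [gemodificeerd zetmeel, gemodificeerde zetmelen]
    - name: Preservative
      terms: [conserveermiddel, conserveermiddelen, conserveringsmiddel]
    - name: Propellent gas
      terms: [drijfgas, drijfgassen]
    - name: Raising agent
      terms: [rijsmiddel, rijsmiddelen]
    - name: Sequestrant
      terms: [complexvormer, complexvormers]
    - name: Stabilizer
      terms: [stabilisator, stabilisatoren]
    - name: Sweetener
      terms: [zoetstof, zoetstoffen]
    - name: Thickener
      terms: [verdikkingsmiddel, verdikkingsmiddelen]
  # "source of" / "rich in" style remarks represent natural content
  natural_content_phrases:
    - bron van
    - rijk aan
    - natuurlijke bron van
    - van nature rijk aan
    - bevat van nature
    - source of
    - rich in
  # "added" / "fortified with" style wordings
  fortification_phrases:
    - verrijkt met
    - toegevoegd
    - toegevoegde
    - met toegevoegd
    - met extra
    - added
    - fortified with
    - enriched with
  # Other vitamin/mineral names that disqualify a generic match when they
  # immediately follow the generic word.  The specific terms of all
  # configured nutrients are always added to this list at load time.
  qualifier_terms:
    - a
    - c
    - d
    - d3
    - e
    - k
    - k2
    - b1
    - b2
    - b3
    - b5
    - b6
    - b7
    - b8
    - ijzer
    - jodium
    - selenium
    - koper
    - magnesium
    - kalium
    - fosfor
    - mangaan
    - chroom
    - molybdeen
    - fluoride
    - biotine
    - niacine
    - thiamine
    - riboflavine
    - pantotheenzuur
  # prefixes under which a term still counts as the leading component of a
  # compound token (e.g. "tricalciumcitraat")
  compound_prefixes: [mono, di, tri, tetra]
  # proximity window (tokens) for additive-context and remark detection
  context_window: 3

beverage_rule:
  # foods in these groups are beverages (7.5%-of-DRI cutoff per 100 mL)
  food_groups:
    - Drinks
  # subgroups of other food groups that also count as beverages
  subgroups:
    - milk
    - chocolate milk
    - condensed milk
    - coffee milk/cream
    - buttermilk
    - dairy drinks
    - liquid breakfast

eligibility:
  # groups governed by legislation other than the general labeling rules
  ineligible_groups:
    - Foods and formulae for infants and young children
    - Foods for specific medical purposes
    - Total diet replacement for weight control
    - Food supplements
  treat_unclassified_as_ineligible: true
  # the eligible food-group vocabulary of the source database
  food_groups:
    - Bread
    - Bread filling
    - Cereals and cereal products
    - Cheese and cheese substitutes
    - Composite meals
    - Drinks
    - Eggs
    - Fish, shellfish, crustacean
    - Fruit
    - Meat replacers
    - Meat, cold cuts, and poultry
    - Milk, milk products, and milk replacers
    - Miscellaneous
    - Nuts and seeds
    - Oils and fats
    - Potatoes and other tubers
    - Pulses
    - Sauces
    - Snacks (sweet and savory)
    - Soup
    - Vegetables

classifier:
  # step 7 searches legal name and mandatory particulars; the food name is
  # searched too only when this flag is on
  search_food_name: false
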