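"""Independent brute-force re-implementation of the seven-step decision tree.

Written as one literal nested conditional over regex matching, sharing no
code with the package, so that agreement between the two is evidence rather
than tautology.
"""

from __future__ import annotations

import re
import unicodedata

INELIGIBLE_GROUPS = {
    "Foods and formulae for infants and young children",
    "Foods for specific medical purposes",
    "Total diet replacement for weight control",
    "Food supplements",
}
BEVERAGE_GROUPS = {"Drinks"}
BEVERAGE_SUBGROUPS = {
    "milk", "chocolate milk", "condensed milk", "coffee milk/cream",
    "buttermilk", "dairy drinks", "liquid breakfast",
}
DRI = {"calcium": 800.0, "folic_acid": 200.0, "vitamin_b12": 2.5, "zinc": 10.0}
VALUE_COLUMNS = {
    "calcium": ["calcium"],
    "folic_acid": ["dfe", "folic_acid"],
    "vitamin_b12": ["vitamin_b12"],
    "zinc": ["zinc"],
}
TERMS = {
    "calcium": [
        "calcium", "calciumcarbonaat", "calciumfosfaat", "dicalciumfosfaat",
        "calciumlactaat", "tricalciumcitraat", "calciumcitraat",
        "calciumzouten van orthofosforzuur", "dicalciumdicitraat",
        "calciumhydroxide",
    ],
    "folic_acid": [
        "foliumzuur", "b9", "b11", "folaat", "tetrahydrofolaat",
        "polyglytamaat", "pfteroylmonoglutaminezuur", "folic acid",
        "folinezuur", "foliumzout",
    ],
    "vitamin_b12": ["b12", "cobalamine", "cyanocobalamine"],
    "zinc": [
        "zink", "zinklactaat", "zink lactaat", "zinksulfaat", "zink sulfaat",
        "zinkoxide", "zink oxide", "zinkgluconaat", "zink gluconaat",
        "zinkcitraat", "zink citraat",
    ],
}
EXCLUSIONS = {"calcium": ["calcium-d-pantothenaat", "calcium-d-pantothenate"]}
GENERIC = [
    "vitamines en mineralen", "vitaminen en mineralen", "vitamine en mineralen",
    "vitamine", "vitaminen", "vitamines", "mineralen", "mineraal",
]
QUALIFIERS = (
    {"a", "c", "d", "d3", "e", "k", "k2", "b1", "b2", "b3", "b5", "b6", "b7",
     "b8", "ijzer", "jodium", "selenium", "koper", "magnesium", "kalium",
     "fosfor", "mangaan", "chroom", "molybdeen", "fluoride", "biotine",
     "niacine", "thiamine", "riboflavine", "pantotheenzuur"}
    | {t.split()[0] for terms in TERMS.values() for t in terms}
)
ADDITIVE_CLASSES = [
    "voedingszuur", "zuur", "acid", "zuurteregelaar", "zuurteregelaars",
    "antiklontermiddel", "anti-klontermiddel", "antischuimmiddel",
    "antioxidant", "antioxidanten", "anti-oxidant", "vulstof", "vulstoffen",
    "kleurstof", "kleurstoffen", "kleur", "emulgator", "emulgatoren",
    "smeltzout", "smeltzouten", "verstevigingsmiddel", "smaakversterker",
    "smaakversterkers", "meelverbeteraar", "schuimmiddel", "geleermiddel",
    "glansmiddel", "bevochtigingsmiddel", "gemodificeerd zetmeel",
    "conserveermiddel", "conserveermiddelen", "conserveringsmiddel",
    "drijfgas", "rijsmiddel", "complexvormer", "complexvormers",
    "stabilisator", "stabilisatoren", "zoetstof", "zoetstoffen",
    "verdikkingsmiddel", "verdikkingsmiddelen",
]
NATURAL = ["bron van", "rijk aan", "natuurlijke bron van", "van nature rijk aan",
           "bevat van nature", "source of", "rich in"]
FORTIF = ["verrijkt met", "toegevoegd", "toegevoegde", "met toegevoegd",
          "met extra", "added", "fortified with", "enriched with"]


def _norm(text: str) -> str:
    out = []
    for ch in text:
        d = unicodedata.normalize("NFKD", ch)
        base = "".join(c for c in d if not unicodedata.combining(c))
        out.append(base[0] if base else " ")
    return "".join(out).lower()


def _term_positions(text: str, nutrient: str) -> list[int]:
    for pattern in EXCLUSIONS.get(nutrient, []):
        text = text.replace(pattern, " " * len(pattern))
    positions = []
    for term in TERMS[nutrient]:
        esc = re.escape(term)
        rx = re.compile(rf"(?<![a-z0-9])(?:mono|di|tri|tetra)?{esc}")
        for m in rx.finditer(text):
            positions.append(m.start())
        if re.fullmatch(r"b\d+", term):
            for m in re.finditer(rf"(?<![a-z0-9])vitamine-?{esc}", text):
                positions.append(m.start())
    return sorted(set(positions))


def _phrase_before(text: str, pos: int, phrases: list[str]) -> bool:
    prefix = text[:pos]
    for phrase in phrases:
        if re.search(
            rf"(?<![a-z]){re.escape(phrase)}\s+(?:[^\s,;:()]+\s+){{0,2}}$", prefix
        ):
            return True
    return False


def _in_additive_context(text: str, pos: int) -> bool:
    prefix = text[:pos]
    for cls in ADDITIVE_CLASSES:
        esc = re.escape(cls)
        if re.search(rf"(?<![a-z]){esc}\s*\([^)]*$", prefix):
            return True  # open bracket group headed by the class
        if re.search(rf"(?<![a-z]){esc}\s*:[^;]*$", prefix):
            return True  # colon scope
        if re.search(rf"(?<![a-z]){esc}\s+(?:[^\s,;:()]+\s+){{0,2}}$", prefix):
            return True  # adjacent, no hard separator
    return False


def _generic_positions(text: str) -> list[int]:
    positions = []
    for term in GENERIC:
        esc = re.escape(term)
        for m in re.finditer(rf"(?<![a-z]){esc}(?![a-z])", text):
            rest = text[m.end():]
            nxt = re.match(r"\s+([^\s,;:()/]+)", rest)
            if nxt:
                word = nxt.group(1).strip(".")
                if word in QUALIFIERS or any(
                    len(q) > 2 and word.startswith(q) for q in QUALIFIERS
                ):
                    continue
            positions.append(m.start())
    return sorted(set(positions))


def _generic_present(text: str) -> bool:
    return bool(_generic_positions(text))


def oracle_classify(record, nutrient: str) -> str:
    group = record.food_group
    if group is None or str(group).strip() == "" or group in INELIGIBLE_GROUPS:
        return "ineligible"

    value = None
    for col in VALUE_COLUMNS[nutrient]:
        if col in record.nutrient_values:
            value = float(record.nutrient_values[col])
            break

    beverage = group in BEVERAGE_GROUPS or (
        record.food_subgroup is not None and record.food_subgroup in BEVERAGE_SUBGROUPS
    )
    threshold = DRI[nutrient] * (0.075 if beverage else 0.15)

    def step7() -> str:
        saw_natural = False
        for text in (record.legal_name, record.mandatory_particulars):
            if not text:
                continue
            t = _norm(text)
            positions = _term_positions(t, nutrient) + _generic_positions(t)
            for pos in positions:
                if _phrase_before(t, pos, FORTIF):
                    return "fortified"
                if _phrase_before(t, pos, NATURAL):
                    saw_natural = True
        return "non_fortified" if saw_natural else "non_fortified"

    if value is None:
        return step7()
    if value < threshold:
        return step7()
    ingredients = _norm(record.ingredient_list or "")
    positions = _term_positions(ingredients, nutrient)
    if not positions:
        if _generic_present(ingredients):
            return "fortified"
        return step7()
    flags = [
        (
            _in_additive_context(ingredients, pos),
            _phrase_before(ingredients, pos, NATURAL),
        )
        for pos in positions
    ]
    if all(additive for additive, _ in flags):
        return step7()
    plain = [1 for additive, natural in flags if not additive and not natural]
    if any(natural for _, natural in flags) and not plain:
        return "non_fortified"
    return "fortified"
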