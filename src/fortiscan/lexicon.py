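"""Text matching over Dutch ingredient lists and label fields.

Dutch writes fortificant mixtures as single compound words ("zinklactaat",
"calciumcarbonaat"), so a search term matches both as a standalone token and
as the leading component of a longer compound token, optionally behind a
multiplicity prefix (mono/di/tri/tetra, as in "tricalciumcitraat").  All
matching is case-insensitive and diacritics-insensitive.

Context matters as much as the match itself: a nutrient name governed by a
functional ingredient class ("stabilisator: calciumcarbonaat") is a food
additive, and one preceded by "bron van" / "rijk aan" is a statement about
natural content.  Those context flags are attached to every match and drive
steps 4-7 of the decision tree.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .model import Lexicon, NutrientSpec

# characters that split tokens; hyphens and periods stay inside tokens so
# that "calcium-d-pantothenaat" and "b12" survive as units
_SEPARATORS = set(",;:()[]{}/\\|")
_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}
_B_NUMBER = re.compile(r"^b\d+$")


def normalize(text: str) -> str:
    """Lowercase and strip diacritics; the canonical matching form.

    Length-preserving (one output char per input char) so that match spans
    computed on the normalized string index the original text too.
    """
    out = []
    for ch in text:
        decomposed = unicodedata.normalize("NFKD", ch)
        base = "".join(c for c in decomposed if not unicodedata.combining(c))
        out.append(base[0] if base else " ")
    return "".join(out).lower()


@dataclass(frozen=True)
class Token:
    text: str  # normalized
    start: int
    end: int
    index: int
    bracket_openers: tuple[int, ...] = ()  # token index before each open bracket
    colon_opener: Optional[int] = None  # token index before the governing ':'


@dataclass
class TokenizedText:
    raw: str
    tokens: list[Token] = field(default_factory=list)
    # positions of hard ingredient separators (commas/semicolons)
    hard_seps: list[int] = field(default_factory=list)
    # positions of any non-whitespace separator (incl. brackets, colons, slashes)
    soft_seps: list[int] = field(default_factory=list)

    def hard_sep_between(self, left: Token, right: Token) -> bool:
        return any(left.end <= p < right.start for p in self.hard_seps)

    def any_sep_between(self, left: Token, right: Token) -> bool:
        return any(left.end <= p < right.start for p in self.soft_seps)


def tokenize(text: str) -> TokenizedText:
    """Split on commas, semicolons, colons, brackets, slashes and whitespace.

    Tracks, for every token, which bracket groups it sits in (by the index of
    the token immediately before the opening bracket) and which colon scope
    governs it (a ':' scope runs until the next semicolon, a closing bracket,
    or the end of the text).
    """
    doc = TokenizedText(raw=text)
    norm = normalize(text)
    n = len(norm)
    bracket_stack: list[int] = []  # opener token indices
    colon: Optional[int] = None
    colon_depth = 0
    i = 0
    while i < n:
        ch = norm[i]
        if ch.isspace() or ch in _SEPARATORS:
            if ch in _SEPARATORS:
                doc.soft_seps.append(i)
            if ch in ",;":
                doc.hard_seps.append(i)
                if ch == ";" and colon is not None and len(bracket_stack) <= colon_depth:
                    colon = None
            if ch == ":":
                colon = doc.tokens[-1].index if doc.tokens else None
                colon_depth = len(bracket_stack)
            elif ch in _OPEN:
                bracket_stack.append(doc.tokens[-1].index if doc.tokens else -1)
            elif ch in _CLOSE:
                if bracket_stack:
                    bracket_stack.pop()
                if colon is not None and len(bracket_stack) < colon_depth:
                    colon = None
            i += 1
            continue
        j = i
        while j < n and not norm[j].isspace() and norm[j] not in _SEPARATORS:
            j += 1
        token_text = norm[i:j].strip(".'\"*")
        if token_text:
            doc.tokens.append(
                Token(
                    text=token_text,
                    start=i,
                    end=j,
                    index=len(doc.tokens),
                    bracket_openers=tuple(o for o in bracket_stack if o >= 0),
                    colon_opener=colon,
                )
            )
        i = j
    return doc


@dataclass(frozen=True)
class TermMatch:
    """One lexicon hit inside a searched text."""

    term: str
    span: tuple[int, int]  # 0-based half-open offsets in the searched text
    token_indices: tuple[int, ...]
    in_additive_context: bool = False
    in_natural_content_remark: bool = False
    in_fortification_remark: bool = False


def _token_matches_word(
    token: str, word: str, prefixes: Sequence[str], compounds: bool
) -> bool:
    if token == word:
        return True
    if not compounds:
        return False
    if len(token) > len(word) and token.startswith(word):
        return True
    for p in prefixes:
        if token.startswith(p + word) and len(token) >= len(p) + len(word):
            return True
    # "B12" style terms also hide inside "vitamineb12" / "vitamine-b12"
    if _B_NUMBER.match(word):
        for glued in (f"vitamine{word}", f"vitamine-{word}", f"vit.{word}", f"vit{word}"):
            if token == glued or token.startswith(glued):
                return True
    return False


def _find_occurrences(
    doc: TokenizedText,
    term: str,
    prefixes: Sequence[str] = (),
    compounds: bool = False,
) -> list[tuple[int, ...]]:
    """Token-index tuples where ``term`` occurs.

    Multi-word terms need adjacent tokens with nothing but whitespace between
    them; only the first word of a multi-word term may sit inside a compound.
    """
    words = term.split()
    hits: list[tuple[int, ...]] = []
    tokens = doc.tokens
    for start in range(len(tokens) - len(words) + 1):
        ok = True
        for offset, word in enumerate(words):
            tok = tokens[start + offset]
            allow_compound = compounds and offset == 0 and len(words) == 1
            if not _token_matches_word(tok.text, word, prefixes, allow_compound):
                ok = False
                break
            if offset > 0 and doc.any_sep_between(tokens[start + offset - 1], tok):
                ok = False
                break
        if ok:
            hits.append(tuple(range(start, start + len(words))))
    return hits


def _dedupe_longest(matches: list[TermMatch]) -> list[TermMatch]:
    """Overlapping matches collapse onto the longest term (ties: earliest)."""
    chosen: list[TermMatch] = []
    for m in sorted(matches, key=lambda m: (-len(m.term), m.span)):
        if all(m.span[1] <= c.span[0] or m.span[0] >= c.span[1] for c in chosen):
            chosen.append(m)
    return sorted(chosen, key=lambda m: m.span)


def _attach_context(doc: TokenizedText, matches: list[TermMatch], lex: Lexicon) -> list[TermMatch]:
    out = []
    for m in matches:
        natural, fortification = _remark_flags(doc, m, lex)
        out.append(
            replace(
                m,
                in_additive_context=detect_additive_context(doc, m, lex),
                in_natural_content_remark=natural,
                in_fortification_remark=fortification,
            )
        )
    return out


def find_specific_terms(
    text: Optional[str], spec: NutrientSpec, lex: Lexicon
) -> list[TermMatch]:
    """All matches of one nutrient's search terms in ``text``.

    Exclusion patterns (e.g. calcium-D-pantothenate for calcium) remove any
    match that lies inside them; overlapping hits collapse onto the longest
    term; surviving matches carry additive-context and remark flags.
    """
    if not text:
        return []
    doc = tokenize(text)
    excluded: set[int] = set()
    for pattern in spec.exclusion_patterns:
        for idxs in _find_occurrences(doc, pattern, compounds=False):
            excluded.update(idxs)
        # an exclusion pattern written as one compound token also excludes it
        for tok in doc.tokens:
            if pattern.replace(" ", "") in tok.text.replace(" ", ""):
                excluded.add(tok.index)
    raw: list[TermMatch] = []
    for term in spec.specific_terms:
        for idxs in _find_occurrences(doc, term, lex.compound_prefixes, compounds=True):
            if excluded.intersection(idxs):
                continue
            span = (doc.tokens[idxs[0]].start, doc.tokens[idxs[-1]].end)
            raw.append(TermMatch(term=term, span=span, token_indices=idxs))
    return _attach_context(doc, _dedupe_longest(raw), lex)


def find_generic_terms(
    text: Optional[str], lex: Lexicon, all_specs: Iterable[NutrientSpec] = ()
) -> list[TermMatch]:
    """Generic vitamin/mineral wordings not qualified by a micronutrient name.

    "vitaminen en mineralen" is generic; "vitamine C" is not, because the
    generic word is immediately qualified by a specific micronutrient name.
    The qualifier vocabulary is the lexicon's list plus every specific term of
    the supplied nutrient specs.
    """
    if not text:
        return []
    doc = tokenize(text)
    qualifiers = set(lex.qualifier_terms)
    for spec in all_specs:
        qualifiers.update(spec.specific_terms)
    raw: list[TermMatch] = []
    for term in lex.generic_terms:
        for idxs in _find_occurrences(doc, term, compounds=False):
            span = (doc.tokens[idxs[0]].start, doc.tokens[idxs[-1]].end)
            raw.append(TermMatch(term=term, span=span, token_indices=idxs))
    kept = []
    for m in _dedupe_longest(raw):
        last = doc.tokens[m.token_indices[-1]]
        if last.index + 1 < len(doc.tokens):
            nxt = doc.tokens[last.index + 1]
            if not doc.any_sep_between(last, nxt) and _is_qualifier(nxt.text, qualifiers):
                continue  # "vitamine C" and friends: not generic
        kept.append(m)
    return _attach_context(doc, kept, lex)


def _is_qualifier(token: str, qualifiers: set[str]) -> bool:
    for q in qualifiers:
        head = q.split()[0]
        if token == head:
            return True
        if len(head) > 2 and token.startswith(head):
            return True
    return False


def detect_additive_context(doc: TokenizedText, match: TermMatch, lex: Lexicon) -> bool:
    """Is the matched term governed by a functional ingredient class?

    True when a class name opens the bracket or colon group the match sits in
    ("verdikkingsmiddel (calciumalginaat)", "antioxidant: zinkgluconaat"), or
    when the class name is one of the few tokens immediately before the match
    with no ingredient separator (comma/semicolon) in between.
    """
    class_last_indices: set[int] = set()
    occurrences: list[tuple[int, ...]] = []
    for term in lex.additive_class_terms:
        for idxs in _find_occurrences(doc, term, compounds=False):
            occurrences.append(idxs)
            class_last_indices.add(idxs[-1])
    if not occurrences:
        return False
    first = doc.tokens[match.token_indices[0]]
    # (a) group opened at a class name
    for opener in first.bracket_openers:
        if opener in class_last_indices:
            return True
    if first.colon_opener is not None and first.colon_opener in class_last_indices:
        return True
    # (b) class name within the window straight before the match
    window = lex.context_window
    for idxs in occurrences:
        last = idxs[-1]
        if first.index - window <= last < first.index:
            if not doc.hard_sep_between(doc.tokens[last], first):
                return True
    return False


def _remark_flags(doc: TokenizedText, match: TermMatch, lex: Lexicon) -> tuple[bool, bool]:
    first = doc.tokens[match.token_indices[0]]
    window = lex.context_window

    def phrase_before(phrases: Sequence[str]) -> bool:
        for phrase in phrases:
            for idxs in _find_occurrences(doc, phrase, compounds=False):
                last = idxs[-1]
                if first.index - window <= last < first.index:
                    return True
        return False

    return phrase_before(lex.natural_content_phrases), phrase_before(
        lex.fortification_phrases
    )


def detect_remarks(doc: TokenizedText, match: TermMatch, lex: Lexicon) -> tuple[bool, bool]:
    """(natural-content, fortification) remark flags for one match."""
    return _remark_flags(doc, match, lex)
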