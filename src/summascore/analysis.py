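"""Language-aware morpho-syntactic analysis of summary statements.

Every downstream rubric computation consumes the token / sentence / entity
structure produced here.  The module defines the analysis contract
(:class:`Token`, :class:`AnalyzedStatement`) and ships a deterministic
rule-based analyzer (:class:`FallbackAnalyzer`) that needs no model
download: a regex word/number tokenizer, terminal-punctuation sentence
splitting with an abbreviation guard, a per-language suffix-stripping
lemmatizer, and rule-based entity detection (honorific + capitalized-word
person rule, a small place gazetteer, numeric date/duration/quantity
patterns).

Statistical backends (e.g. a spaCy pipeline) can be plugged in behind the
same interface via :func:`get_analyzer`; their label sets are mapped into
the closed entity label set used here.

Coordinates are 0-based and half-open throughout: ``char_span = (s, e)``
means ``text[s:e]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .errors import ConfigurationError

SUPPORTED_LANGUAGES = ("en", "de")

#: Closed entity label set.  Backend-specific labels are mapped into it.
ENTITY_LABELS = ("PERSON", "PLACE", "DATE", "DURATION", "QUANTITY", "NONE")

# Token pattern: decimal numbers (both '.' and ',' separators), degree
# units like "°C", hyphenated words ("left-sided"), plain words, then any
# single non-space symbol.
_TOKEN_RE = re.compile(r"\d+(?:[.,]\d+)?|°\w+|\w+(?:-\w+)*|[^\w\s]", re.UNICODE)

_TERMINAL_PUNCT = {".", "!", "?"}

# Honorifics suppress sentence breaks after a following "." and anchor the
# person rule.  Lower-cased comparison.
HONORIFICS = {"mr", "mrs", "ms", "dr", "prof", "herr", "frau", "fr", "hr"}

# Minimal built-in gazetteer so capitalized country/city names are PLACE,
# never PERSON ("treated in China").
PLACES = {
    "china", "germany", "deutschland", "usa", "england", "france", "spain",
    "italy", "india", "brazil", "munich", "münchen", "berlin", "london",
    "paris", "augsburg", "hamburg", "vienna", "wien", "africa", "asia",
    "europe", "europa", "amerika",
}

_TIME_UNITS_EN = {"second", "minute", "hour", "day", "week", "month", "year"}
_TIME_UNITS_DE = {"sekunde", "minute", "stunde", "tag", "woche", "monat", "jahr"}

_DETERMINERS = {"a", "an", "the", "der", "die", "das", "ein", "eine", "einen",
                "einem", "einer"}
_ADPOSITIONS = {"in", "on", "at", "with", "of", "for", "to", "by", "mit",
                "von", "bei", "auf", "für", "zu", "über", "ueber", "nach"}
_PRONOUNS = {"he", "she", "it", "they", "i", "we", "you", "er", "sie", "es",
             "wir", "ich", "that", "which", "who"}
_AUXILIARIES = {"is", "are", "was", "were", "has", "have", "had", "be",
                "been", "ist", "sind", "war", "waren", "hat", "haben",
                "wird", "wurde", "presents", "stellt"}


@dataclass(frozen=True)
class Token:
    """One token of an analyzed statement.

    ``char_span`` is a half-open ``(start, end)`` offset pair into the
    original text; ``head_index`` equals ``index`` for a sentence root.
    """

    surface: str
    lemma: str
    index: int
    char_span: tuple[int, int]
    pos: str
    head_index: int
    dep_label: str
    entity_label: str = "NONE"

    @property
    def is_punct(self) -> bool:
        return self.pos == "PUNCT"

    @property
    def is_alpha(self) -> bool:
        return self.surface.replace("-", "").isalpha()

    @property
    def is_number(self) -> bool:
        return bool(re.fullmatch(r"\d+(?:[.,]\d+)?", self.surface))


@dataclass(frozen=True)
class AnalyzedStatement:
    """Token / sentence / entity structure for one statement.

    ``sentences`` are half-open token-index ranges partitioning the token
    list; ``entities`` are ``(token_range, label)`` pairs, each range lying
    within one sentence.
    """

    statement_id: str
    language: str
    text: str
    tokens: tuple[Token, ...]
    sentences: tuple[tuple[int, int], ...]
    entities: tuple[tuple[tuple[int, int], str], ...] = ()

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def lemmas(self) -> list[str]:
        return [t.lemma for t in self.tokens]

    def sentence_of(self, token_index: int) -> tuple[int, int]:
        for start, end in self.sentences:
            if start <= token_index < end:
                return (start, end)
        raise IndexError(f"token index {token_index} outside all sentences")


def lemmatize(word: str, language: str) -> str:
    """Deterministic suffix-stripping lemmatizer.

    English: lower-case; strip possessive ``'s``; ``-ies`` -> ``y``; strip a
    final ``-s`` (but not ``-ss``).  German: lower-case, fold ``ß`` -> ``ss``
    and strip one inflection suffix of ``-em/-en/-es/-e``.  The same
    function normalizes lexicon entries at load time, so matching stays
    consistent even where the stripped stem is not a dictionary lemma.
    """
    w = word.lower()
    if language == "de":
        w = w.replace("ß", "ss")
        for suffix in ("em", "en", "es"):
            if w.endswith(suffix) and len(w) - 2 >= 3:
                return w[:-2]
        if w.endswith("e") and len(w) - 1 >= 3:
            return w[:-1]
        return w
    # English rules
    if w.endswith("'s") and len(w) > 2:
        w = w[:-2]
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("s") and not w.endswith("ss") and len(w) > 3:
        return w[:-1]
    return w


def _coarse_pos(surface: str) -> str:
    low = surface.lower()
    if re.fullmatch(r"\d+(?:[.,]\d+)?", surface):
        return "NUM"
    if not re.search(r"\w", surface):
        return "PUNCT"
    if low in _DETERMINERS:
        return "DET"
    if low in _ADPOSITIONS:
        return "ADP"
    if low in _PRONOUNS:
        return "PRON"
    if low in _AUXILIARIES:
        return "AUX"
    return "NOUN"


class FallbackAnalyzer:
    """Deterministic rule-based analyzer; the default backend.

    Person detection is rule-based: an honorific followed by a capitalized
    word (both languages), or — English only — a title-cased word that is
    not sentence-initial and not in the place gazetteer, merged with
    adjacent capitalized words.  The capitalized-word route is disabled for
    German because ordinary German nouns are capitalized; German statements
    therefore rely on the metadata-name route during scoring.
    """

    name = "fallback"

    def __call__(self, text: str, language: str,
                 statement_id: str = "") -> AnalyzedStatement:
        raw = [(m.group(0), m.start(), m.end())
               for m in _TOKEN_RE.finditer(text)]
        sentences = self._split_sentences(raw)
        tokens = self._build_tokens(raw, sentences, language)
        entities = self._detect_entities(tokens, sentences, language)
        tokens = self._label_tokens(tokens, entities)
        return AnalyzedStatement(
            statement_id=statement_id,
            language=language,
            text=text,
            tokens=tuple(tokens),
            sentences=tuple(sentences),
            entities=tuple(entities),
        )

    # -- segmentation -------------------------------------------------

    def _split_sentences(self, raw) -> list[tuple[int, int]]:
        sentences: list[tuple[int, int]] = []
        start = 0
        for i, (surf, _, _) in enumerate(raw):
            if surf in _TERMINAL_PUNCT:
                prev = raw[i - 1][0].lower() if i > start else ""
                if surf == "." and prev in HONORIFICS:
                    continue  # "Mr." does not end the sentence
                sentences.append((start, i + 1))
                start = i + 1
        if start < len(raw):
            sentences.append((start, len(raw)))
        return sentences

    def _build_tokens(self, raw, sentences, language) -> list[Token]:
        tokens: list[Token] = []
        for s_start, s_end in sentences:
            heads, deps = self._parse_sentence(raw, s_start, s_end)
            for i in range(s_start, s_end):
                surf, cs, ce = raw[i]
                pos = _coarse_pos(surf)
                lemma = (lemmatize(surf, language)
                         if re.search(r"[^\W\d_]", surf, re.UNICODE)
                         else surf.lower())
                tokens.append(Token(
                    surface=surf, lemma=lemma, index=i, char_span=(cs, ce),
                    pos=pos, head_index=heads[i - s_start],
                    dep_label=deps[i - s_start]))
        return tokens

    def _parse_sentence(self, raw, start, end):
        """Shallow dependency assignment: one root per sentence; numbers
        attach to a following content word as numeric modifiers; everything
        else attaches to the root."""
        pos = [_coarse_pos(raw[i][0]) for i in range(start, end)]
        root = next((i for i, p in enumerate(pos) if p in ("NOUN", "PROPN")),
                    0 if end > start else None)
        heads, deps = [], []
        for local, p in enumerate(pos):
            if local == root:
                heads.append(start + local)
                deps.append("ROOT")
            elif (p == "NUM" and local + 1 < len(pos)
                  and pos[local + 1] in ("NOUN", "PROPN")):
                heads.append(start + local + 1)
                deps.append("nummod")
            elif p == "PUNCT":
                heads.append(start + root)
                deps.append("punct")
            else:
                heads.append(start + root)
                deps.append("dep")
        return heads, deps

    # -- entities ------------------------------------------------------

    def _detect_entities(self, tokens, sentences, language):
        entities: list[tuple[tuple[int, int], str]] = []
        taken: set[int] = set()

        def claim(rng: tuple[int, int], label: str) -> None:
            if any(i in taken for i in range(*rng)):
                return
            entities.append((rng, label))
            taken.update(range(*rng))

        for s_start, s_end in sentences:
            self._person_spans(tokens, s_start, s_end, language, claim)
            self._place_spans(tokens, s_start, s_end, claim)
            self._numeric_spans(tokens, s_start, s_end, language, claim)
        entities.sort(key=lambda e: e[0])
        return entities

    def _person_spans(self, tokens, s_start, s_end, language, claim):
        i = s_start
        while i < s_end:
            surf = tokens[i].surface
            # honorific route (both languages): "Mr" ["."] "Smith"
            if surf.lower().rstrip(".") in HONORIFICS and surf[:1].isupper():
                j = i + 1
                if j < s_end and tokens[j].surface == ".":
                    j += 1
                if j < s_end and tokens[j].surface[:1].isupper() \
                        and tokens[j].is_alpha:
                    claim((i, j + 1), "PERSON")
                    i = j + 1
                    continue
            # capitalized-word route, English only
            if language == "en" and self._person_candidate(tokens, i, s_start):
                left = i
                while left - 1 >= s_start and self._capitalized_name(tokens[left - 1]):
                    left -= 1
                right = i + 1
                while right < s_end and self._person_candidate(tokens, right, s_start):
                    right += 1
                claim((left, right), "PERSON")
                i = right
                continue
            i += 1

    @staticmethod
    def _capitalized_name(tok: Token) -> bool:
        return (tok.is_alpha and len(tok.surface) >= 2
                and tok.surface[0].isupper() and tok.surface[1:].islower()
                and tok.surface.lower() not in PLACES
                and tok.surface.lower() not in HONORIFICS)

    def _person_candidate(self, tokens, i, s_start) -> bool:
        return i > s_start and self._capitalized_name(tokens[i])

    def _place_spans(self, tokens, s_start, s_end, claim):
        for i in range(s_start, s_end):
            if tokens[i].surface.lower() in PLACES and tokens[i].surface[:1].isupper():
                claim((i, i + 1), "PLACE")

    def _numeric_spans(self, tokens, s_start, s_end, language, claim):
        time_units = _TIME_UNITS_EN if language == "en" else _TIME_UNITS_DE
        age_tail = {"old"} if language == "en" else {"alt"}
        i = s_start
        while i < s_end:
            if tokens[i].is_number:
                # age pattern: "67 year old" -> DATE
                if (i + 2 < s_end
                        and tokens[i + 1].lemma in {"year", "jahr"}
                        and tokens[i + 2].lemma in age_tail):
                    claim((i, i + 3), "DATE")
                    i += 3
                    continue
                # duration pattern: "3 months" -> DURATION
                if i + 1 < s_end and tokens[i + 1].lemma in time_units:
                    claim((i, i + 2), "DURATION")
                    i += 2
                    continue
                claim((i, i + 1), "QUANTITY")
            i += 1

    @staticmethod
    def _label_tokens(tokens, entities) -> list[Token]:
        labels = {}
        for (start, end), label in entities:
            for i in range(start, end):
                labels[i] = label
        return [
            replace(t, entity_label=labels[t.index])
            if t.index in labels and not t.is_punct else t
            for t in tokens
        ]


class SpacyAnalyzer:
    """Adapter for a spaCy pipeline; available only when spacy and the
    requested model are installed.  Backend entity labels are mapped into
    the closed set (GPE/LOC -> PLACE, PER/PERSON -> PERSON, DATE -> DATE,
    TIME -> DURATION, QUANTITY/CARDINAL -> QUANTITY, others -> NONE)."""

    _LABEL_MAP = {
        "PERSON": "PERSON", "PER": "PERSON", "GPE": "PLACE", "LOC": "PLACE",
        "DATE": "DATE", "TIME": "DURATION", "QUANTITY": "QUANTITY",
        "CARDINAL": "QUANTITY",
    }

    def __init__(self, model_name: str):
        try:
            import spacy  # type: ignore
        except ImportError as exc:
            raise ConfigurationError(
                f"analyzer backend {model_name!r} requires spacy, which is "
                f"not installed; use analyzer 'fallback'") from exc
        try:
            self._nlp = spacy.load(model_name)
        except OSError as exc:
            raise ConfigurationError(
                f"spaCy model {model_name!r} is not available") from exc
        self.name = model_name

    def __call__(self, text, language, statement_id=""):
        doc = self._nlp(text)
        tokens = []
        for tok in doc:
            label = self._LABEL_MAP.get(tok.ent_type_, "NONE")
            tokens.append(Token(
                surface=tok.text, lemma=tok.lemma_.lower(), index=tok.i,
                char_span=(tok.idx, tok.idx + len(tok.text)),
                pos=tok.pos_, head_index=tok.head.i, dep_label=tok.dep_,
                entity_label="NONE" if tok.is_punct else label))
        sentences = tuple((s.start, s.end) for s in doc.sents)
        entities = tuple(
            ((e.start, e.end), self._LABEL_MAP.get(e.label_, "NONE"))
            for e in doc.ents if e.label_ in self._LABEL_MAP)
        return AnalyzedStatement(statement_id, language, text,
                                 tuple(tokens), sentences, entities)


def get_analyzer(name: str = "fallback"):
    """Resolve an analyzer handle from a configuration name."""
    if name == "fallback":
        return FallbackAnalyzer()
    return SpacyAnalyzer(name)


def analyze(text: str, language: str, backend=None,
            statement_id: str = "") -> AnalyzedStatement:
    """Analyze one statement.

    The language must be supplied explicitly (it is carried by the batch
    file, never guessed).  Empty or whitespace-only text yields a valid
    zero-token structure.
    """
    if language not in SUPPORTED_LANGUAGES:
        raise ConfigurationError(
            f"unsupported language {language!r}; expected one of "
            f"{SUPPORTED_LANGUAGES}")
    if len(text) > 10_000:
        raise ConfigurationError("statement exceeds 10,000 characters")
    backend = backend or FallbackAnalyzer()
    return backend(text, language, statement_id=statement_id)


def detect_person_spans(stmt: AnalyzedStatement) -> list[tuple[tuple[int, int], str]]:
    """Return every PERSON entity span as ``(token_range, matched_text)``,
    ordered by position; empty list when none."""
    spans = []
    for (start, end), label in stmt.entities:
        if label == "PERSON":
            cs = stmt.tokens[start].char_span[0]
            ce = stmt.tokens[end - 1].char_span[1]
            spans.append(((start, end), stmt.text[cs:ce]))
    return spans
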