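"""Scoring vocabularies and term identification.

Three tab-separated lexicon files drive the rubric:

* ``sq_<lang>.tsv`` — semantic qualifiers (paired qualitative descriptors
  such as acute/chronic) with their antonym partner and a match mode:
  ``lemma-exact`` for whole-token matches or ``token-prefix`` for
  designated prefixes ("hyper" inside "hypertension");
* ``thesaurus_<lang>.tsv`` — a curated categorized medical vocabulary
  (findings, diagnoses, anatomical terms, places) in the spirit of an
  adapted MeSH subset; multi-token forms are supported and the format also
  accepts bulk imports from MeSH descriptor exports;
* ``si_units.tsv`` — measurement-unit symbols used to spot raw
  (untransformed) measurement mentions such as "39.4 °C".

All comparisons run on lemmatized, case-folded forms; lexicon entries are
normalized with the same lemmatizer as statement tokens so both sides of a
comparison stay consistent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

from .analysis import AnalyzedStatement, lemmatize
from .errors import LexiconError

TERM_CATEGORIES = ("finding", "diagnosis", "anatomical", "duration", "date",
                   "place", "si-unit")
MATCH_MODES = ("lemma-exact", "token-prefix")

# Vital-sign labels introducing a raw measurement even without a unit
# symbol ("Temperature: 39.4").  Multi-word labels are matched on lemmas.
VITAL_LABELS = {
    "en": [("temperature",), ("temp",), ("pulse",), ("heart", "rate"),
           ("blood", "pressure"), ("respiratory", "rate"), ("bp",),
           ("oxygen", "saturation")],
    "de": [("temperatur",), ("puls",), ("blutdruck",), ("atemfrequenz",),
           ("rr",)],
}

_TIME_UNIT_LEMMAS = {"second", "minute", "hour", "day", "week", "month",
                     "year", "sekunde", "minute", "stunde", "tag", "woche",
                     "monat", "jahr"}
_AGE_TAIL = {"old", "alt"}


@dataclass(frozen=True)
class SQEntry:
    """One semantic qualifier: its normalized form, language scope, match
    mode, and the form of its opposing qualifier (if paired)."""
    form: str
    language: str           # en | de | both
    match_mode: str          # lemma-exact | token-prefix
    antonym: str | None
    lemma: str               # normalized form used for matching


@dataclass(frozen=True)
class TermEntry:
    """One categorized thesaurus term; ``lemmas`` is its normalized token
    sequence (multi-token forms are matched contiguously)."""
    form: str
    category: str
    language: str
    lemmas: tuple[str, ...]

    @property
    def lemma_key(self) -> str:
        return " ".join(self.lemmas)


@dataclass(frozen=True)
class SQMatch:
    """A semantic-qualifier occurrence in a statement."""
    entry: SQEntry
    token_index: int
    matched_surface: str
    whole_token: bool


@dataclass(frozen=True)
class ClassifiedTerm:
    """A categorized term occurrence: contiguous token range + category."""
    token_range: tuple[int, int]
    category: str
    matched_form: str
    lemma_key: str


def _entry_lemma(form: str, language: str) -> str:
    lang = "en" if language == "both" else language
    return lemmatize(form, lang)


def _read_tsv(path: str | Path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            rows.append((lineno, stripped.split("\t")))
    return rows


def lexicon_checksum(path: str | Path) -> str:
    """SHA-256 of the raw file bytes, for provenance reporting."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_sq_lexicon(path: str | Path) -> list[SQEntry]:
    """Load a semantic-qualifier lexicon and enforce antonym symmetry.

    Columns: form, language, match_mode, antonym (empty for unpaired).
    An antonym named by one entry must itself be present and must name the
    first entry back; asymmetry is a load error naming both forms.
    """
    entries: dict[tuple[str, str], SQEntry] = {}
    for lineno, cols in _read_tsv(path):
        if len(cols) < 3:
            raise LexiconError(f"{path}:{lineno}: expected at least 3 columns")
        form = cols[0].strip().lower()
        language = cols[1].strip()
        mode = cols[2].strip()
        antonym = cols[3].strip().lower() if len(cols) > 3 and cols[3].strip() else None
        if mode not in MATCH_MODES:
            raise LexiconError(
                f"{path}:{lineno}: unknown match_mode {mode!r} for {form!r}")
        if language not in ("en", "de", "both"):
            raise LexiconError(
                f"{path}:{lineno}: unknown language {language!r} for {form!r}")
        key = (form, language)
        if key in entries:
            raise LexiconError(f"{path}:{lineno}: duplicate entry {key}")
        entries[key] = SQEntry(form=form, language=language, match_mode=mode,
                               antonym=antonym,
                               lemma=_entry_lemma(form, language))
    by_form: dict[str, SQEntry] = {e.form: e for e in entries.values()}
    for e in entries.values():
        if e.antonym is None:
            continue
        partner = by_form.get(e.antonym)
        if partner is None or partner.antonym != e.form:
            raise LexiconError(
                f"asymmetric antonym pair: {e.form!r} lists {e.antonym!r} "
                f"but the mirror entry is missing or points elsewhere")
    return sorted(entries.values(), key=lambda e: (e.form, e.language))


def load_thesaurus(path: str | Path) -> list[TermEntry]:
    """Load a categorized term thesaurus (columns: form, category,
    language)."""
    entries: dict[tuple[str, str, str], TermEntry] = {}
    for lineno, cols in _read_tsv(path):
        if len(cols) < 3:
            raise LexiconError(f"{path}:{lineno}: expected 3 columns")
        form = cols[0].strip().lower()
        category = cols[1].strip()
        language = cols[2].strip()
        if category not in TERM_CATEGORIES:
            raise LexiconError(
                f"{path}:{lineno}: unknown category {category!r} for {form!r}")
        key = (form, language, category)
        if key in entries:
            raise LexiconError(f"{path}:{lineno}: duplicate entry {key}")
        lang = "en" if language == "both" else language
        lemmas = tuple(lemmatize(w, lang) for w in form.split())
        entries[key] = TermEntry(form=form, category=category,
                                 language=language, lemmas=lemmas)
    return sorted(entries.values(), key=lambda e: (e.form, e.category))


def load_si_units(path: str | Path) -> set[str]:
    """Load SI-unit symbols (columns: symbol, dimension); matching is
    case-insensitive on the symbol."""
    units = set()
    for lineno, cols in _read_tsv(path):
        if not cols[0].strip():
            raise LexiconError(f"{path}:{lineno}: empty unit symbol")
        units.add(cols[0].strip().lower())
    return units


def _applicable(entry_language: str, statement_language: str) -> bool:
    return entry_language in (statement_language, "both")


def find_semantic_qualifiers(
    stmt: AnalyzedStatement,
    lex: list[SQEntry],
    context_filter: bool = True,
) -> list[SQMatch]:
    """Find every semantic-qualifier occurrence in a statement.

    A ``lemma-exact`` entry matches a token whose lemma equals the entry
    lemma; a ``token-prefix`` entry matches as a proper prefix of a longer
    token ("hyper" in "hypertension", ``whole_token=False``) or as the
    whole token.  With ``context_filter`` on (default), a whole-token
    qualifier only counts when it is directly followed by an alphabetic
    token in the same sentence — i.e. it plausibly modifies a concept —
    while prefix hits always qualify; this approximates checking the
    semantic context against the syntactic analysis.

    The result counts occurrences: the same qualifier appearing twice
    yields two matches.  Matches are ordered by token index.
    """
    applicable = [e for e in lex if _applicable(e.language, stmt.language)]
    exact = {}
    for e in applicable:
        if e.match_mode == "lemma-exact":
            exact.setdefault(e.lemma, e)
    prefixes = [e for e in applicable if e.match_mode == "token-prefix"]

    matches: list[SQMatch] = []
    for tok in stmt.tokens:
        if tok.is_punct:
            continue
        hit: SQMatch | None = None
        if tok.lemma in exact:
            hit = SQMatch(exact[tok.lemma], tok.index, tok.surface, True)
        else:
            low = tok.surface.lower()
            for e in prefixes:
                if low.startswith(e.form) and len(low) > len(e.form):
                    hit = SQMatch(e, tok.index, e.form, False)
                    break
                if tok.lemma == e.lemma:
                    hit = SQMatch(e, tok.index, tok.surface, True)
                    break
        if hit is None:
            continue
        if context_filter and hit.whole_token:
            s_start, s_end = stmt.sentence_of(tok.index)
            nxt = tok.index + 1
            if not (nxt < s_end and stmt.tokens[nxt].is_alpha):
                continue
        matches.append(hit)
    return matches


def classify_terms(stmt: AnalyzedStatement,
                   thesaurus: list[TermEntry]) -> list[ClassifiedTerm]:
    """Tag categorized term occurrences in a statement.

    Thesaurus forms are matched on contiguous lemma sequences; overlapping
    candidates are resolved longest-match-first ("loss of appetite" beats
    "appetite"), ties broken by earliest start.  Numeric date / duration
    patterns ("67 year old", "3 months") and gazetteer places recognized
    during analysis are classified by rule even when absent from the
    thesaurus.
    """
    lemmas = stmt.lemmas()
    n = len(lemmas)
    applicable = [e for e in thesaurus if _applicable(e.language, stmt.language)]

    candidates: list[ClassifiedTerm] = []
    for entry in applicable:
        k = len(entry.lemmas)
        if k == 0:
            continue
        for i in range(0, n - k + 1):
            if tuple(lemmas[i:i + k]) == entry.lemmas:
                # multi-token forms must not straddle a sentence break
                if any(t.is_punct for t in stmt.tokens[i:i + k]):
                    continue
                candidates.append(ClassifiedTerm(
                    (i, i + k), entry.category, entry.form, entry.lemma_key))

    # rule-based date / duration spans from the analysis entities
    for (start, end), label in stmt.entities:
        if label == "DATE":
            candidates.append(ClassifiedTerm(
                (start, end), "date",
                " ".join(t.surface for t in stmt.tokens[start:end]),
                " ".join(lemmas[start:end])))
        elif label == "DURATION":
            candidates.append(ClassifiedTerm(
                (start, end), "duration",
                " ".join(t.surface for t in stmt.tokens[start:end]),
                " ".join(lemmas[start:end])))
        elif label == "PLACE":
            candidates.append(ClassifiedTerm(
                (start, end), "place",
                " ".join(t.surface for t in stmt.tokens[start:end]),
                " ".join(lemmas[start:end])))

    # longest-match-wins, ties by earliest start; drop duplicates
    candidates.sort(key=lambda c: (-(c.token_range[1] - c.token_range[0]),
                                   c.token_range[0], c.category))
    chosen: list[ClassifiedTerm] = []
    taken: set[int] = set()
    for cand in candidates:
        rng = range(*cand.token_range)
        if any(i in taken for i in rng):
            continue
        chosen.append(cand)
        taken.update(rng)
    chosen.sort(key=lambda c: c.token_range)
    return chosen


def _raw_measurement_spans(stmt: AnalyzedStatement,
                           units: set[str]) -> list[tuple[int, int]]:
    """Token spans of raw measurement mentions: a number adjacent to an SI
    unit, or a vital-sign label followed by (optional colon and) a number.
    Overlapping spans are merged so one mention counts once."""
    spans: list[tuple[int, int]] = []
    toks = stmt.tokens
    n = len(toks)
    for i, tok in enumerate(toks):
        if tok.is_number:
            if i + 1 < n and toks[i + 1].surface.lower() in units:
                spans.append((i, i + 2))
            elif i > 0 and toks[i - 1].surface.lower() in units:
                spans.append((i - 1, i + 1))
    labels = VITAL_LABELS.get(stmt.language, [])
    lemmas = stmt.lemmas()
    for lab in labels:
        k = len(lab)
        for i in range(0, n - k):
            if tuple(lemmas[i:i + k]) != lab:
                continue
            j = i + k
            if j < n and toks[j].surface == ":":
                j += 1
            if j < n and toks[j].is_number:
                end = j + 1
                if end < n and toks[end].surface.lower() in units:
                    end += 1
                spans.append((i, end))
    if not spans:
        return []
    spans.sort()
    merged = [spans[0]]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


def count_transformation_evidence(
    stmt: AnalyzedStatement,
    thesaurus: list[TermEntry],
    units: set[str],
) -> tuple[int, int, list[ClassifiedTerm], list[tuple[int, int]]]:
    """Count transformed vs. raw-measurement mentions.

    A *transformed* mention is a thesaurus finding or diagnosis term (the
    learner restated data as medical terminology); a *raw* mention is a
    number adjacent to an SI unit or a labeled vital-sign reading left
    untransformed.  Returns ``(T, N, transformed_terms, raw_spans)``; a
    term inside a raw mention never counts toward T.
    """
    raw_spans = _raw_measurement_spans(stmt, units)
    terms = classify_terms(stmt, thesaurus)

    def in_raw(rng: tuple[int, int]) -> bool:
        return any(not (rng[1] <= s or e <= rng[0]) for s, e in raw_spans)

    transformed = [t for t in terms
                   if t.category in ("finding", "diagnosis")
                   and not in_raw(t.token_range)]
    return len(transformed), len(raw_spans), transformed, raw_spans


def attach_qualifiers(
    stmt: AnalyzedStatement,
    sq_matches: list[SQMatch],
    terms: list[ClassifiedTerm],
    window: int = 3,
) -> list[tuple[SQMatch, str | None]]:
    """Anchor each qualifier occurrence to the concept it qualifies.

    A qualifier attaches to a classified term when it was matched as a
    prefix inside one of the term's tokens, or when it precedes the term's
    first token within ``window`` tokens in the same sentence.  Qualifiers
    with no anchored concept map to ``None``.
    """
    out: list[tuple[SQMatch, str | None]] = []
    for m in sq_matches:
        concept: str | None = None
        for t in terms:
            start, end = t.token_range
            if not m.whole_token and start <= m.token_index < end:
                concept = t.lemma_key
                break
            if m.token_index < start <= m.token_index + window:
                same = stmt.sentence_of(m.token_index) == stmt.sentence_of(start)
                if same:
                    concept = t.lemma_key
                    break
        out.append((m, concept))
    return out
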