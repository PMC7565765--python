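"""The six-category rubric scorers.

Each category reduces an analyzed learner statement, the lexicons, and the
expert profile to raw quantities and then maps them through fixed
thresholds onto an ordinal score:

* **semantic qualifiers** — occurrence count ``q`` of paired qualitative
  descriptors; ``q < 2 -> 0``, ``2 <= q <= 4 -> 1``, ``q > 4 -> 2``;
* **narrowing** — miss ratio ``r = (E - M) / E`` of expert terms the
  learner failed to include; ``r > 0.75 -> 0``,
  ``0.25 <= r <= 0.75 -> 1``, ``r < 0.25 -> 2``;
* **transformation** — ``t = max(0, T - N/2) / (T_e + L)`` where ``T`` is
  the learner's transformed-term count, ``N`` the raw-measurement count,
  ``T_e`` the expert's transformed count and ``L`` a statement-length
  factor (token count / divisor); ``t < 0.16 -> 0``,
  ``0.16 <= t <= 0.7 -> 1``, ``t > 0.7 -> 2``;
* **accuracy** — 0 iff a learner qualifier and an expert qualifier are
  antonym partners anchored to the same concept, else 1;
* **patient name** — 1 iff a person entity is present or a configured
  name variant occurs in the text, else 0;
* **global rating** — sum ``s`` of the five scores; ``s <= 2 -> 0``,
  ``2 < s <= 5 -> 1``, ``s > 5 -> 2``.

Raw counts and ratios are always exposed alongside the ordinal score so a
feedback layer can display the underlying quantity rather than the coarse
step value.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field

from .analysis import AnalyzedStatement, analyze, detect_person_spans
from .errors import ConfigurationError
from . import lexicon as lx
from .reference import ExpertProfile, VPReference, build_expert_profile
from .resources import Resources, RubricThresholds, ScoringOptions

CATEGORIES = ("sq", "narrowing", "transformation", "accuracy", "name",
              "global")
#: Valid ordinal range per category (inclusive).
CATEGORY_RANGES = {"sq": (0, 2), "narrowing": (0, 2),
                   "transformation": (0, 2), "accuracy": (0, 1),
                   "name": (0, 1), "global": (0, 2)}


@dataclass(frozen=True)
class CategoryResult:
    """One category's outcome: ordinal score, raw quantities, evidence.

    ``evidence`` holds labelled half-open character spans into the learner
    statement.
    """
    category: str
    score: int
    raw: dict
    evidence: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self):
        lo, hi = CATEGORY_RANGES[self.category]
        if not lo <= self.score <= hi:
            raise ValueError(
                f"{self.category} score {self.score} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class RatingResult:
    """Complete six-category rating of one statement."""
    statement_id: str
    results: dict[str, CategoryResult]
    provenance: dict = field(default_factory=dict)

    def score(self, category: str) -> int:
        return self.results[category].score

    def scores(self) -> dict[str, int]:
        return {c: self.results[c].score for c in CATEGORIES}

    def __post_init__(self):
        missing = set(CATEGORIES) - set(self.results)
        if missing:
            raise ValueError(f"missing categories: {sorted(missing)}")
        s = self.results["global"].raw.get("s")
        expected = sum(self.results[c].score for c in CATEGORIES
                       if c != "global")
        if s != expected:
            raise ValueError(f"global raw sum {s} != category sum {expected}")

    def to_dict(self) -> dict:
        return {
            "statement_id": self.statement_id,
            "categories": {
                c: {
                    "score": r.score,
                    "raw": r.raw,
                    "evidence": [list(e) for e in r.evidence],
                }
                for c, r in self.results.items()
            },
            "provenance": self.provenance,
        }


# -- individual scorers ----------------------------------------------------

def score_semantic_qualifiers(q: int,
                              thresholds: RubricThresholds | None = None,
                              evidence=()) -> CategoryResult:
    """Map a qualifier count onto the 0/1/2 scale."""
    th = thresholds or RubricThresholds()
    if q < 0:
        raise ValueError("qualifier count must be non-negative")
    if q < th.sq_low:
        score = 0
    elif q <= th.sq_high:
        score = 1
    else:
        score = 2
    return CategoryResult("sq", score, {"q": q}, tuple(evidence))


def score_narrowing(E: int, M: int,
                    thresholds: RubricThresholds | None = None,
                    evidence=()) -> CategoryResult:
    """Score differential-diagnosis narrowing from expert-term overlap.

    ``E`` expert terms, ``M`` of them matched by the learner (capped at
    ``E``); the miss ratio ``r = (E - M) / E`` drives the score.
    """
    th = thresholds or RubricThresholds()
    if E < 1:
        raise ConfigurationError(
            "narrowing undefined: expert reference yields no scorable terms")
    M = min(max(M, 0), E)
    r = (E - M) / E
    if r > th.narrow_zero:
        score = 0
    elif r >= th.narrow_two:
        score = 1
    else:
        score = 2
    return CategoryResult("narrowing", score,
                          {"E": E, "M": M, "r": r}, tuple(evidence))


def score_transformation(T: int, N: int, T_e: int, L: float,
                         thresholds: RubricThresholds | None = None,
                         evidence=()) -> CategoryResult:
    """Score transformation of raw data into medical terminology.

    ``t = max(0, T - N/2) / (T_e + L)``; the numerator is clamped at zero
    because a surplus of raw mentions cannot push the 0-2 scale below
    "none".
    """
    th = thresholds or RubricThresholds()
    if min(T, N, T_e) < 0 or L < 0:
        raise ValueError("transformation counts must be non-negative")
    if T_e + L <= 0:
        raise ConfigurationError(
            "transformation undefined: expert transformed count and length "
            "factor are both zero")
    t = max(0.0, T - N / 2) / (T_e + L)
    if t < th.transform_zero:
        score = 0
    elif t <= th.transform_two:
        score = 1
    else:
        score = 2
    return CategoryResult(
        "transformation", score,
        {"T": T, "N": N, "T_e": T_e, "L": L, "t": t}, tuple(evidence))


def find_contradictions(
    learner_sq: list[tuple[lx.SQMatch, str | None]],
    expert_sq: list[tuple[lx.SQMatch, str | None]],
    lenient: bool = False,
) -> list[dict]:
    """Antonymous qualifier pairs between learner and expert.

    Strict mode (default) requires both qualifiers to be anchored to the
    same concept lemma; lenient mode pairs antonyms anywhere in the two
    statements.
    """
    out = []
    for lm, lconcept in learner_sq:
        if lm.entry.antonym is None:
            continue
        for em, econcept in expert_sq:
            if em.entry.form != lm.entry.antonym:
                continue
            anchored = (lconcept is not None and lconcept == econcept)
            if anchored or lenient:
                out.append({
                    "learner_qualifier": lm.entry.form,
                    "expert_qualifier": em.entry.form,
                    "concept": lconcept if anchored else None,
                })
    return out


def score_accuracy(learner_sq, expert_sq, lenient: bool = False,
                   evidence=()) -> CategoryResult:
    """Binary factual-accuracy check via contradicting qualifier use."""
    contradictions = find_contradictions(learner_sq, expert_sq,
                                         lenient=lenient)
    return CategoryResult("accuracy", 0 if contradictions else 1,
                          {"contradictions": contradictions},
                          tuple(evidence))


def score_patient_name(person_spans, stmt: AnalyzedStatement,
                       name_forms=()) -> CategoryResult:
    """Binary patient-name check: entity route or metadata-name route.

    The metadata route matches any configured name variant as a
    token-bounded, case-insensitive substring of the statement, which
    covers languages where the entity recognizer cannot find person names.
    """
    if person_spans:
        (start, end), matched = person_spans[0]
        cs = stmt.tokens[start].char_span[0]
        ce = stmt.tokens[end - 1].char_span[1]
        return CategoryResult("name", 1,
                              {"route": "entity", "matched": matched},
                              ((cs, ce, "person"),))
    low = stmt.text.lower().replace("ß", "ss")
    for form in name_forms:
        for m in re.finditer(re.escape(form), low):
            before = low[m.start() - 1] if m.start() > 0 else " "
            after = low[m.end()] if m.end() < len(low) else " "
            if not before.isalnum() and not after.isalnum():
                return CategoryResult(
                    "name", 1, {"route": "metadata", "matched": form},
                    ((m.start(), m.end(), "person"),))
    return CategoryResult("name", 0, {"route": None, "matched": None})


def global_rating(scores, thresholds: RubricThresholds | None = None) -> CategoryResult:
    """Sum the five category scores and map onto the 0/1/2 scale."""
    th = thresholds or RubricThresholds()
    scores = list(scores)
    if len(scores) != 5:
        raise ValueError("global rating expects exactly five category scores")
    s = sum(scores)
    if s <= th.global_zero:
        score = 0
    elif s <= th.global_one:
        score = 1
    else:
        score = 2
    return CategoryResult("global", score, {"s": s})


# -- orchestration ---------------------------------------------------------

def _term_char_span(stmt: AnalyzedStatement, rng: tuple[int, int]) -> tuple[int, int]:
    return (stmt.tokens[rng[0]].char_span[0],
            stmt.tokens[rng[1] - 1].char_span[1])


def _count_matches(profile: ExpertProfile, stmt: AnalyzedStatement,
                   learner_terms, options: ScoringOptions):
    """Expert terms matched by the learner: a term matches when its lemma
    sequence occurs contiguously in the learner lemma sequence (or, with
    the fuzzy toggle, when a learner term's lemma key is close enough by
    edit ratio).  Counted once per expert term, so M <= E."""
    lemmas = [t.lemma for t in stmt.tokens if not t.is_punct]
    joined = " ".join(lemmas)
    learner_keys = {t.lemma_key for t in learner_terms}
    matched = []
    for term in profile.expert_terms:
        hit = term.lemma_key in learner_keys
        if not hit and term.lemma_key:
            hit = bool(re.search(
                rf"(?:^| ){re.escape(term.lemma_key)}(?: |$)", joined))
        if not hit and options.fuzzy_term_match:
            hit = any(
                difflib.SequenceMatcher(None, term.lemma_key, k).ratio()
                >= options.fuzzy_threshold
                for k in learner_keys)
        if hit:
            matched.append(term)
    return matched


class Rater:
    """Rate learner statements for one virtual patient.

    Builds the expert profile once, then applies the analysis, lexicon and
    scoring stages to each statement.  The rater contains no randomness
    and no VP-specific code paths; degenerate learner text yields low
    scores, never exceptions.
    """

    def __init__(self, resources: Resources, ref: VPReference):
        if ref.language != resources.provenance.get("language", ref.language):
            raise ConfigurationError(
                f"reference language {ref.language!r} does not match loaded "
                f"lexicon language "
                f"{resources.provenance.get('language')!r}")
        self.resources = resources
        self.reference = ref
        self.profile = build_expert_profile(
            ref, resources.sq_lexicon, resources.thesaurus, resources.units,
            analyzer=resources.analyzer,
            sq_context_filter=resources.options.sq_context_filter)

    def rate(self, text: str, statement_id: str = "") -> RatingResult:
        res = self.resources
        th = res.thresholds
        opts = res.options
        stmt = analyze(text, self.reference.language, backend=res.analyzer,
                       statement_id=statement_id)

        # lexicon stage
        sq_matches = lx.find_semantic_qualifiers(
            stmt, res.sq_lexicon, context_filter=opts.sq_context_filter)
        learner_terms = lx.classify_terms(stmt, res.thesaurus)
        T, N, transformed, raw_spans = lx.count_transformation_evidence(
            stmt, res.thesaurus, res.units)
        anchored = lx.attach_qualifiers(stmt, sq_matches, learner_terms)

        # semantic qualifiers
        if opts.sq_count_mode == "types":
            q = len({m.entry.form for m in sq_matches})
        else:
            q = len(sq_matches)
        sq_ev = tuple(
            (stmt.tokens[m.token_index].char_span[0],
             stmt.tokens[m.token_index].char_span[0] + len(m.matched_surface),
             f"sq:{m.entry.form}")
            for m in sq_matches)
        r_sq = score_semantic_qualifiers(q, th, evidence=sq_ev)

        # narrowing
        matched = _count_matches(self.profile, stmt, learner_terms, opts)
        narrow_ev = tuple(
            (*_term_char_span(stmt, t.token_range), f"term:{t.category}")
            for t in learner_terms)
        r_narrow = score_narrowing(self.profile.E, len(matched), th,
                                   evidence=narrow_ev)
        r_narrow.raw["matched_terms"] = [t.lemma_key for t in matched]

        # transformation
        L = stmt.n_tokens / th.length_factor_divisor
        trans_ev = tuple(
            (*_term_char_span(stmt, t.token_range), "transformed")
            for t in transformed
        ) + tuple(
            (*_term_char_span(stmt, rng), "raw-measurement")
            for rng in raw_spans)
        r_trans = score_transformation(T, N, self.profile.expert_transformed,
                                       L, th, evidence=trans_ev)

        # accuracy
        r_acc = score_accuracy(anchored, list(self.profile.expert_sq),
                               lenient=opts.lenient_contradictions)

        # patient name
        r_name = score_patient_name(detect_person_spans(stmt), stmt,
                                    self.profile.name_forms)

        # global
        five = [r_sq.score, r_narrow.score, r_trans.score, r_acc.score,
                r_name.score]
        r_global = global_rating(five, th)

        return RatingResult(
            statement_id=statement_id or stmt.statement_id,
            results={"sq": r_sq, "narrowing": r_narrow,
                     "transformation": r_trans, "accuracy": r_acc,
                     "name": r_name, "global": r_global},
            provenance={**res.provenance,
                        "vp_id": self.reference.vp_id,
                        "thresholds": vars(th)},
        )


def rate_statement(text: str, language: str, ref: VPReference,
                   resources: Resources,
                   statement_id: str = "") -> RatingResult:
    """Convenience wrapper: build a Rater for ``ref`` and rate one text."""
    if language != ref.language:
        raise ConfigurationError(
            f"statement language {language!r} does not match reference "
            f"language {ref.language!r}")
    return Rater(resources, ref).rate(text, statement_id=statement_id)
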