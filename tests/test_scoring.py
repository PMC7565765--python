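"""Rubric score formulas, threshold boundaries, and orchestration."""

import pytest
from hypothesis import given, settings, strategies as st

import summascore as s

from conftest import TB_STATEMENT


# -- threshold boundaries (the step functions of the rubric) -------------

@pytest.mark.parametrize("q,expected", [
    (0, 0), (1, 0), (2, 1), (3, 1), (4, 1), (5, 2), (9, 2)])
def test_semantic_qualifier_thresholds(q, expected):
    assert s.score_semantic_qualifiers(q).score == expected


@pytest.mark.parametrize("E,M,expected", [
    # r = (E - M) / E; r > 0.75 -> 0; 0.25 <= r <= 0.75 -> 1; r < 0.25 -> 2
    (1000, 249, 0),   # r = 0.751
    (4, 1, 1),        # r = 0.75 inclusive
    (4, 3, 1),        # r = 0.25 inclusive
    (1000, 751, 2),   # r = 0.249
    (4, 4, 2),        # perfect overlap
    (4, 0, 0),        # no overlap
])
def test_narrowing_thresholds(E, M, expected):
    result = s.score_narrowing(E, M)
    assert result.score == expected
    assert result.raw["r"] == pytest.approx((E - M) / E)


@pytest.mark.parametrize("T,N,T_e,L,expected", [
    (0, 0, 2, 0.5, 0),
    (2, 0, 2, 0.5, 2),     # t = 0.8
    (2, 2, 2, 0.5, 1),     # t = 0.4
    (159, 0, 1000, 0, 0),  # t = 0.159
    (160, 0, 1000, 0, 1),  # t = 0.16 inclusive
    (700, 0, 1000, 0, 1),  # t = 0.70 inclusive
    (701, 0, 1000, 0, 2),  # t = 0.701
    (0, 10, 2, 0.5, 0),    # numerator clamped at zero
])
def test_transformation_thresholds(T, N, T_e, L, expected):
    result = s.score_transformation(T, N, T_e, L)
    assert result.score == expected
    assert result.raw["t"] >= 0


@pytest.mark.parametrize("scores,expected", [
    ((0, 1, 1, 1, 0), 1),   # worked example: sum 3
    ((0, 0, 0, 0, 0), 0),
    ((0, 1, 0, 1, 0), 0),   # sum 2 inclusive
    ((2, 1, 1, 1, 0), 1),   # sum 5 inclusive
    ((2, 2, 1, 1, 0), 2),   # sum 6
    ((2, 2, 2, 1, 1), 2),   # maximum attainable sum 8
])
def test_global_rating_thresholds(scores, expected):
    result = s.global_rating(scores)
    assert result.score == expected
    assert result.raw["s"] == sum(scores)


def test_zero_expert_terms_is_configuration_error():
    with pytest.raises(s.ConfigurationError):
        s.score_narrowing(0, 0)


def test_zero_transformation_denominator_is_configuration_error():
    with pytest.raises(s.ConfigurationError):
        s.score_transformation(1, 0, 0, 0.0)


# -- monotonicity properties ---------------------------------------------

@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10))
def test_sq_score_is_monotone(q):
    assert s.score_semantic_qualifiers(q + 1).score >= \
        s.score_semantic_qualifiers(q).score


@settings(max_examples=50, deadline=None)
@given(st.integers(1, 12), st.integers(0, 12))
def test_narrowing_score_anti_monotone_in_miss_ratio(E, M):
    M = min(M, E)
    if M < E:  # one more matched term never lowers the score
        assert s.score_narrowing(E, M + 1).score >= \
            s.score_narrowing(E, M).score


@settings(max_examples=80, deadline=None)
@given(st.tuples(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2),
                 st.integers(0, 1), st.integers(0, 1)),
       st.integers(0, 4))
def test_global_rating_monotone_in_each_category(scores, idx):
    scores = list(scores)
    base = s.global_rating(scores).score
    hi = 2 if idx < 3 else 1
    if scores[idx] < hi:
        scores[idx] += 1
        assert s.global_rating(scores).score >= base


# -- accuracy and name ----------------------------------------------------

def _anchored_sq(res, text, language="en"):
    stmt = s.analyze(text, language, backend=res.analyzer)
    matches = s.find_semantic_qualifiers(stmt, res.sq_lexicon)
    terms = s.classify_terms(stmt, res.thesaurus)
    return s.lexicon.attach_qualifiers(stmt, matches, terms)


def test_antonym_on_shared_concept_is_contradiction(resources_en):
    learner = _anchored_sq(resources_en, "She has chronic cough.")
    expert = _anchored_sq(resources_en, "Acute cough and fever.")
    result = s.score_accuracy(learner, expert)
    assert result.score == 0
    assert result.raw["contradictions"][0]["concept"] == "cough"


def test_identical_statements_cannot_contradict(resources_en):
    text = "Severe chronic cough with fever."
    anchored = _anchored_sq(resources_en, text)
    assert s.score_accuracy(anchored, anchored).score == 1


def test_antonyms_on_different_concepts_do_not_contradict(resources_en):
    learner = _anchored_sq(resources_en, "Chronic fever is present.")
    expert = _anchored_sq(resources_en, "Acute cough and night sweats.")
    assert s.score_accuracy(learner, expert).score == 1
    # the lenient whole-statement mode does pair them
    assert s.score_accuracy(learner, expert, lenient=True).score == 0


def test_patient_name_entity_route(resources_en):
    stmt = s.analyze("Anna Miller presents with cough.", "en")
    result = s.score_patient_name(s.detect_person_spans(stmt), stmt)
    assert result.score == 1
    assert result.raw["route"] == "entity"


def test_patient_name_metadata_route_for_german():
    stmt = s.analyze("Anna Müller klagt über Husten.", "de")
    assert s.detect_person_spans(stmt) == []  # entity route cannot fire
    result = s.score_patient_name([], stmt, ("anna müller", "müller"))
    assert result.score == 1
    assert result.raw["route"] == "metadata"


def test_patient_name_requires_token_boundaries():
    stmt = s.analyze("Scanning revealed nothing.", "en")
    # "anna" occurs inside "Scanning"? no - but "can" does not match either
    assert s.score_patient_name([], stmt, ("can",)).score == 0


def test_empty_statement_scores_no_name():
    stmt = s.analyze("", "en")
    assert s.score_patient_name([], stmt, ("anna",)).score == 0


# -- orchestration ---------------------------------------------------------

def test_worked_example_full_rating(rater_en):
    result = rater_en.rate(TB_STATEMENT, statement_id="tb")
    assert result.scores() == {"sq": 0, "narrowing": 1, "transformation": 1,
                               "accuracy": 1, "name": 0, "global": 1}
    assert result.results["sq"].raw["q"] == 1
    assert result.results["narrowing"].raw["M"] == 3
    # evidence spans stay inside the statement text
    for cat in result.results.values():
        for start, end, _ in cat.evidence:
            assert 0 <= start < end <= len(TB_STATEMENT)


def test_empty_statement_rates_low_not_raising(rater_en):
    result = rater_en.rate("", statement_id="empty")
    assert result.scores() == {"sq": 0, "narrowing": 0, "transformation": 0,
                               "accuracy": 1, "name": 0, "global": 0}


def test_rating_is_deterministic(rater_en):
    a = rater_en.rate(TB_STATEMENT, statement_id="x")
    b = rater_en.rate(TB_STATEMENT, statement_id="x")
    assert a == b


def test_global_sum_invariant(rater_en):
    result = rater_en.rate("Severe cough with weight loss and fever.",
                           statement_id="y")
    five = sum(result.results[c].score for c in
               ("sq", "narrowing", "transformation", "accuracy", "name"))
    assert result.results["global"].raw["s"] == five


def test_language_mismatch_rejected(resources_en, ref_de):
    with pytest.raises(s.ConfigurationError):
        s.rate_statement("Husten.", "de", ref_de, resources_en)


def test_repeated_learner_terms_cannot_inflate_overlap(rater_en):
    once = rater_en.rate("Cough.", statement_id="a")
    thrice = rater_en.rate("Cough, cough and cough.", statement_id="b")
    assert once.results["narrowing"].raw["M"] == \
        thrice.results["narrowing"].raw["M"] == 1
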