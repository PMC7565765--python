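# Methods

## Scope and model

`summascore` rates clinical summary statements on a six-category rubric:
use of semantic qualifiers, appropriate narrowing of the differential
diagnosis, transformation of information, factual accuracy, use of the
patient's name, and a global rating. The first three are computed as
continuous raw quantities mapped through fixed thresholds onto a 0/1/2
scale; accuracy and name are binary; the global rating thresholds the sum
of the other five. All raw quantities (counts, ratios, evidence spans) are
reported alongside the ordinal scores, so a feedback layer can display the
informative ratio rather than the coarse step value.

Scoring is reference-based, not trained: each virtual patient supplies a
reference bundle (expert statement, patient name, final diagnoses, key
findings) from which an expert profile is derived with the same analysis
and lexicon operations applied to learner statements. There are no
VP-specific code paths and no randomness anywhere in the rater.

## Linguistic analysis

The analysis contract is a token/sentence/entity structure with 0-based,
half-open spans. The shipped backend is deterministic and rule-based:

* **Tokenizer** — a regex over decimal numbers (`39.4` / `38,5`), degree
  units (`°C`), hyphenated and plain words, and single symbols; token
  spans reconstruct the input exactly (property-tested).
* **Sentence splitter** — terminal `.!?`, with a break suppressed after
  honorific abbreviations ("Mr.", "Dr.", "Frau").
* **Lemmatizer** — suffix stripping. English: possessive `'s`,
  `-ies → y`, final `-s` (not `-ss`). German: case-fold, `ß → ss`, strip
  one of `-em/-en/-es/-e`. The `-er` suffix is deliberately not stripped
  (it would mangle *Fieber*, *schwer*). Stems need not be dictionary
  lemmas: lexicon entries pass through the same function at load time, so
  both sides of every comparison are normalized identically.
* **Dependencies** — a shallow tree: one root per sentence, numbers attach
  to a following content word as `nummod` ("3" → "months"), punctuation as
  `punct`, everything else to the root. Only the numeric-modifier relation
  is consumed downstream; qualifier–concept anchoring uses adjacency
  windows instead (see Accuracy).
* **Entities** — a closed label set {PERSON, PLACE, DATE, DURATION,
  QUANTITY, NONE}. Person detection: an honorific followed by a
  capitalized word (both languages), or — English only — a title-cased,
  non-sentence-initial word outside the place gazetteer, merged with
  adjacent capitalized words. The capitalized-word route is off for German
  because ordinary German nouns are capitalized; German name detection
  therefore relies on the metadata route during scoring, which mirrors how
  statistical pipelines also fail on German patient names in this domain.
  Numeric patterns yield DATE ("67 year old"), DURATION ("3 months") and
  QUANTITY spans; a small built-in gazetteer yields PLACE ("China").

A statistical backend (spaCy pipeline) can be plugged in behind the same
interface when installed; its entity labels are mapped into the closed
set. The packaged test suite runs entirely on the rule-based backend.

## Lexicons

Tab-separated, UTF-8, `#`-commented files; all matching is on lemmatized,
case-folded forms.

* `sq_<lang>.tsv` — semantic qualifiers with a symmetric antonym relation
  (enforced at load) and a match mode. `lemma-exact` entries match whole
  tokens; `token-prefix` is restricted to designated prefixes (*hyper*,
  *hypo*, *tachy*, *brady*, …) so "hypertension" surfaces the *hyper*
  qualifier without flooding matches.
* `thesaurus_<lang>.tsv` — a curated categorized vocabulary (findings,
  diagnoses, anatomical terms, places), a few dozen terms per language in
  the spirit of an adapted MeSH subset; the format accepts bulk imports
  from MeSH descriptor exports but does not require them. Multi-token
  forms match contiguous lemma sequences; overlaps resolve
  longest-match-first ("loss of appetite" beats "appetite"), ties by
  earliest start. Date/duration spans are classified by rule even when
  absent from the thesaurus.
* `si_units.tsv` — unit symbols; a number adjacent to one, or a labeled
  vital-sign reading ("Temperature: 39.4"), is a raw measurement mention.
  Overlapping raw spans merge so one reading counts once.

Qualifier counting counts **occurrences** (tokens), not distinct types;
a `types` mode is available. A semantic-context filter (default on)
requires a whole-token qualifier to be directly followed by an alphabetic
token in its sentence — i.e. to plausibly modify a concept — while prefix
hits always count; the filter is configurable because the underlying
requirement ("compare the semantic context") admits several readings.

## Category computations

* **Narrowing** — the expert term set *E* is the union of classified terms
  from the expert statement and the metadata lists, deduplicated by
  (lemma sequence, category); metadata phrases outside the thesaurus still
  count, categorized by the list they came from. An expert term is matched
  (*M*) when its lemma sequence occurs contiguously in the learner's lemma
  sequence; matching is counted once per expert term, so repetition cannot
  inflate *M* and *M* ≤ *E*. *E* = 0 is a configuration error (the ratio
  is undefined), raised when the profile is built. An optional edit-ratio
  fuzzy match (difflib, threshold 0.9) is off by default.
* **Transformation** — *T* counts thesaurus finding/diagnosis occurrences
  outside raw-measurement spans; *N* counts merged raw spans; *T*ₑ is the
  expert's *T*. The statement-length factor is *L* = token count / 25,
  i.e. one typical sentence of credit, making longer statements need
  proportionally more transformed terms; the divisor is configurable and
  recorded in provenance. The numerator is clamped at 0: a surplus of raw
  mentions cannot push a 0–2 scale below "none".
* **Accuracy** — a contradiction is a learner qualifier and an expert
  qualifier that are antonym partners anchored to the same concept. A
  qualifier anchors to a classified term when matched as a prefix inside
  it or when preceding its first token within 3 tokens in the same
  sentence. A lenient whole-statement pairing mode exists (off by
  default) for analyses without usable structure; unanchored pairing
  over-triggers and is not the default.
* **Patient name** — entity route first; otherwise any configured name
  variant (given name, surname, full name, honorific-stripped,
  case-folded, ß-folded) matched as a token-bounded substring. The route
  that fired is recorded.
* **Global** — thresholds on the sum; with accuracy and name contributing
  0/1, the maximum sum is 8.

Thresholds live in one dataclass (`RubricThresholds`) with validation of
their ordering; all defaults are the rubric's published cut points, and
the boundary behaviour (all inequalities inclusive exactly as stated) is
pinned by tests at q ∈ {1,2,4,5}, r ∈ {0.249,0.25,0.75,0.751},
t ∈ {0.159,0.16,0.7,0.701}, s ∈ {2,3,5,6}.

## Agreement statistics

Rating pairs cross-tabulate with the automatic score on rows and the
manual score on columns, always over the full label range of the category.
Percent agreement is 100 · trace/total; Cohen's κ is the unweighted
nominal form (categories are treated nominally; weighted κ is out of
scope), with bands none/slight (κ ≤ 0.20, including κ ≤ 0), fair (≤ 0.40),
moderate (≤ 0.60), substantial (≤ 0.80), almost perfect (≤ 1.00). A
degenerate matrix whose chance agreement is 1 yields κ = NaN with band
"undefined" rather than an exception; an empty matrix is an input error.
The matrix-based κ is cross-checked in tests against scikit-learn's
pair-based implementation, and sanity properties (κ = 1 on diagonal
matrices, |κ| < 0.05 for 10,000 pairs from independent uniform raters,
invariance under simultaneous row/column label permutation) are asserted.

## Synthetic statements and what they show

The study corpora such a rater is validated on are typically not publicly
deposited, so the test bed is synthetic. The generator assembles
statements from templates in which every rubric quantity is planted by
construction: the number of qualifier occurrences (safe qualifier +
filler-noun phrases whose fillers are outside the thesaurus), the fraction
of expert terms included, extra transformed-term mentions, raw-measurement
sentences (each contributing exactly one raw span), the patient's name,
and optionally a contradiction ("acute cough" against the expert's
"chronic cough"). Unachievable plants (a contradiction with no qualifier
budget or no shared term, a name with no reference name) raise errors
naming the parameter. The planted transformation score is derived from the
planted counts plus the assembled text's token count, since *L* depends on
length.

The master end-to-end property is the round trip: rating a generated
batch with the same resources recovers every planted category score
exactly (≥ 100 statements per run across both languages, seeded).
Generation is deterministic — same seed, byte-identical batch — and all
randomness lives in the generator; the rater has none.

What this does and does not show: the fixtures exercise the full pipeline
(tokenization, lemma matching across German inflection, multi-token terms,
prefix qualifiers, raw-measurement detection, both name routes, anchored
contradictions) under controlled vocabulary, but real learner statements
contain misspellings, out-of-lexicon synonyms, free word order and
ungrammatical fragments that templates do not emulate. Recovery on
fixtures therefore validates the arithmetic and the matching contracts,
not real-world recall of the lexicons; on real data the lexicon coverage
is the binding constraint, which is why the lexicon files are user-
replaceable and checksummed into every report's provenance.

## Numerical and degenerate-input choices

Ratios are computed in double precision directly from integer counts; no
tolerance is applied at threshold comparisons (the boundary cases arise
from exact integer ratios). Empty statements rate (0, 0, 0, 1, 0; global
0) without exceptions. Statement language is always supplied explicitly,
never guessed; a language/lexicon mismatch is a configuration error.
Report JSON is sorted and timing is logged, never asserted — it is
hardware-dependent.

## Known limitations

* The rule-based analyzer has no true part-of-speech or dependency model;
  the accuracy category's anchoring is adjacency-based and will miss
  long-range qualifier–concept relations.
* Bundled lexicons are compact curated lists intended for correctness and
  testing, not production coverage of either language.
* Accuracy detects only qualifier-antonym contradictions — wrong facts
  expressed without antonymous qualifiers pass; the binary category is
  known to be the hardest to automate and to rate reliably by hand.
* German person detection is metadata-dependent by design.
* The narrowing match is exact on lemma sequences by default; synonymous
  expert/learner terms count as misses unless the thesaurus lists both
  under the same form or the fuzzy toggle is enabled.
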