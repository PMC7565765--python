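# summascore

Automatic rubric-based rating of clinical **summary statements** — the one-
to three-sentence patient synopses that learners compose in virtual-patient
(VP) scenarios. The ability to distil a case into such a statement is a
recognized indicator of clinical reasoning skill, and a published rubric
assesses it on six categories. `summascore` computes those six scores
automatically from a rule-based linguistic analysis, curated lexicons and a
per-case expert reference, so learners can receive immediate structured
feedback; it also quantifies how well an automatic rater agrees with a
human one.

It is aimed at medical-education researchers and VP-platform developers who
need a transparent, deterministic, dependency-light scoring engine for
English and German statements.

## The rubric

For a learner statement analyzed into tokens/sentences/entities, with a
qualifier lexicon, a categorized medical thesaurus, an SI-unit list, and an
expert profile derived from the case author's statement plus VP metadata:

| category | raw quantity | score |
|---|---|---|
| semantic qualifiers | occurrence count *q* of paired qualitative descriptors (acute/chronic, mild/severe, …) | *q* < 2 → 0; 2 ≤ *q* ≤ 4 → 1; *q* > 4 → 2 |
| narrowing | miss ratio *r* = (*E* − *M*)/*E* over the expert's *E* key terms, *M* of which the learner includes | *r* > 0.75 → 0; 0.25 ≤ *r* ≤ 0.75 → 1; *r* < 0.25 → 2 |
| transformation | *t* = max(0, *T* − *N*/2) / (*T*ₑ + *L*): transformed terms *T* vs. raw measurements *N*, against the expert's *T*ₑ and a length factor *L* | *t* < 0.16 → 0; 0.16 ≤ *t* ≤ 0.7 → 1; *t* > 0.7 → 2 |
| accuracy | antonymous qualifier pairs (learner vs. expert) anchored to the same concept | contradiction → 0, else 1 |
| patient name | person entity, or metadata name match | found → 1, else 0 |
| global rating | sum *s* of the five scores | *s* ≤ 2 → 0; 2 < *s* ≤ 5 → 1; *s* > 5 → 2 |

Agreement between raters is summarized per category by a confusion matrix,
percent agreement, and unweighted Cohen's κ = (p₀ − pₑ)/(1 − pₑ), banded
none/slight (≤ 0.20), fair, moderate, substantial, almost perfect.

## Worked example

```python
import summascore as s

resources = s.load_resources(language="en")
reference = s.load_reference(
    s.packaged_data_dir() / "examples" / "reference_en.yaml")
statement = ("67 year old patient, presents with a cough that lasted "
             "3 months. Has a smoking history. Has experienced weight loss "
             "and loss of appetite. Green sputum. Earlier diagnosed with "
             "hypertension, treated in China.")
result = s.rate_statement(statement, "en", reference, resources)
```

Printing each category (`examples/rate_worked_example.py`) gives:

```
category          score  raw
sq                   0  {'q': 1}
narrowing            1  {'E': 6, 'M': 3, 'r': 0.5}
transformation       1  {'T': 5, 'N': 0, 'T_e': 6, 'L': 1.6, 't': 0.658}
accuracy             1  {}
name                 0  {'route': None, 'matched': None}
global               1  {'s': 3}
```

One qualifier is found ("hyper" as a prefix inside "hypertension"), below
the 2-qualifier threshold; three of the expert's six key terms appear (miss
ratio 0.5); five transformed terms with no raw measurements give *t* ≈
0.66; no contradicting qualifier use; the patient is never named. The five
scores sum to 3, a global rating of 1.

The other scripts in `examples/` demonstrate the analysis structure, the
agreement statistics, and the synthetic-fixture round trip; the `summascore`
CLI (`rate`, `evaluate`, `gen-fixtures`, `analyze`) wraps the same
functions for batch use.

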