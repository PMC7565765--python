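"""Inspect the linguistic analysis behind the scoring.

Analyzes one sentence with the rule-based fallback backend and prints the
token table (lemma, part of speech, dependency head, entity label) that
the lexicon and scoring stages consume.
"""

import summascore as s

stmt = s.analyze("Mr. Smith presents with a cough that lasted 3 months.",
                 "en")

print(f"{'token':<10} {'lemma':<10} {'pos':<6} {'head':<10} dep/entity")
for tok in stmt.tokens:
    head = stmt.tokens[tok.head_index].surface
    print(f"{tok.surface:<10} {tok.lemma:<10} {tok.pos:<6} {head:<10} "
          f"{tok.dep_label}/{tok.entity_label}")

print("persons:", [text for _, text in s.detect_person_spans(stmt)])

# "3" attaches to "months" as a numeric modifier (nummod), and the
# honorific rule recognizes "Mr. Smith" as a PERSON span.
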