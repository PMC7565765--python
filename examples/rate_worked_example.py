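"""Rate a tuberculosis summary statement against its expert reference.

Loads the bundled English lexicons and the tuberculosis reference bundle,
rates one learner statement, and prints each rubric category's ordinal
score together with the underlying raw quantity.
"""

import summascore as s

STATEMENT = (
    "67 year old patient, presents with a cough that lasted 3 months. "
    "Has a smoking history. Has experienced weight loss and loss of "
    "appetite. Green sputum. Earlier diagnosed with hypertension, "
    "treated in China."
)

resources = s.load_resources(language="en")
reference = s.load_reference(
    s.packaged_data_dir() / "examples" / "reference_en.yaml")
result = s.rate_statement(STATEMENT, "en", reference, resources,
                          statement_id="tb-example")

print("category          score  raw")
for category, cat in result.results.items():
    raw = {k: (round(v, 3) if isinstance(v, float) else v)
           for k, v in cat.raw.items() if not isinstance(v, list)}
    print(f"{category:<16} {cat.score:>5}  {raw}")

# The statement uses only one semantic qualifier ("hyper" inside
# "hypertension"), so that category scores 0; three of the expert's six
# key terms appear (miss ratio 0.5 -> narrowing 1); five transformed
# terms against no raw measurements give transformation 1; no
# contradicting qualifier use (accuracy 1); the patient is never named
# (name 0).  The five scores sum to 3, a global rating of 1.
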