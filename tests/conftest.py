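import pytest

import summascore as s

# Learner summary statement of the tuberculosis worked example.
TB_STATEMENT = (
    "67 year old patient, presents with a cough that lasted 3 months. "
    "Has a smoking history. Has experienced weight loss and loss of "
    "appetite. Green sputum. Earlier diagnosed with hypertension, "
    "treated in China."
)

# Published manual-vs-automatic confusion matrices (automatic on rows,
# manual on columns) for the 125-statement study set, with the validated
# agreement statistics.  The transformation matrix totals 124 and is kept
# out of the kappa expectations.
STUDY_MATRICES = {
    "sq": [[39, 15, 0], [5, 51, 9], [0, 2, 4]],
    "narrowing": [[21, 9, 1], [8, 68, 13], [0, 2, 3]],
    "transformation": [[47, 14, 1], [11, 35, 5], [0, 6, 5]],
    "accuracy": [[5, 2], [12, 106]],
    "name": [[78, 10], [2, 35]],
    "global": [[24, 4, 0], [8, 72, 5], [0, 8, 4]],
}
STUDY_KAPPA = {"sq": 0.557, "narrowing": 0.458, "accuracy": 0.366,
               "name": 0.783, "global": 0.582}
STUDY_AGREEMENT = {"sq": 75.2, "name": 90.4, "global": 80.0}


def study_matrix(category: str) -> s.ConfusionMatrix:
    counts = STUDY_MATRICES[category]
    return s.ConfusionMatrix(category, tuple(range(len(counts))),
                             tuple(tuple(row) for row in counts))


@pytest.fixture(scope="session")
def resources_en() -> s.Resources:
    return s.load_resources(language="en")


@pytest.fixture(scope="session")
def resources_de() -> s.Resources:
    return s.load_resources(language="de")


@pytest.fixture(scope="session")
def ref_en() -> s.VPReference:
    return s.load_reference(
        s.packaged_data_dir() / "examples" / "reference_en.yaml")


@pytest.fixture(scope="session")
def ref_de() -> s.VPReference:
    return s.load_reference(
        s.packaged_data_dir() / "examples" / "reference_de.yaml")


@pytest.fixture(scope="session")
def rater_en(resources_en, ref_en) -> s.Rater:
    return s.Rater(resources_en, ref_en)


@pytest.fixture(scope="session")
def tb_analysis(resources_en) -> s.AnalyzedStatement:
    return s.analyze(TB_STATEMENT, "en", backend=resources_en.analyzer,
                     statement_id="tb")
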