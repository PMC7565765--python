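"""Batch I/O, the synthetic fixture generator, and the CLI."""

import json

import pytest
from click.testing import CliRunner

import summascore as s
from summascore.cli import main as cli_main
from summascore.fixtures import FixtureGenerator

from conftest import STUDY_MATRICES, study_matrix


# -- batch I/O -------------------------------------------------------------

def _records():
    return [
        s.StatementRecord("s1", "vp1", "en", "Severe cough.",
                          {"sq": 0, "global": 1}),
        s.StatementRecord("s2", "vp1", "en", "Fever, 39.4 °C."),
    ]


def test_csv_jsonl_round_trip_identical(tmp_path):
    records = _records()
    csv_path, jsonl_path = tmp_path / "b.csv", tmp_path / "b.jsonl"
    s.write_statements(records, csv_path)
    s.write_statements(records, jsonl_path)
    assert s.read_statements(csv_path) == records
    assert s.read_statements(jsonl_path) == records
    assert s.read_statements(csv_path) == s.read_statements(jsonl_path)


def test_invalid_rows_reported_together(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "statement_id,vp_id,language,text\n"
        "s1,vp1,fr,Bonjour\n"
        "s2,vp1,en,\n"
        "s3,vp1,en,ok\n"
        "s3,vp1,en,duplicate id\n",
        encoding="utf-8")
    with pytest.raises(s.ValidationError) as exc:
        s.read_statements(path)
    messages = "\n".join(exc.value.errors)
    assert "row 2" in messages and "fr" in messages
    assert "row 3" in messages
    assert "row 5" in messages and "duplicate" in messages


def test_pairs_round_trip(tmp_path):
    pairs = s.pairs_from_matrix(study_matrix("name"))
    path = tmp_path / "pairs.csv"
    s.write_pairs(pairs, path)
    assert s.read_pairs(path) == pairs


# -- fixture generator -----------------------------------------------------

def test_same_seed_gives_identical_batches(resources_en, ref_en):
    spec = s.FixtureSpec(seed=11, n=8)
    a = s.generate_fixtures(spec, resources_en, ref_en)
    b = s.generate_fixtures(spec, resources_en, ref_en)
    assert a[0] == b[0]
    assert [t.scores() for t in a[1]] == [t.scores() for t in b[1]]


def test_different_seed_changes_batch(resources_en, ref_en):
    a, _ = s.generate_fixtures(s.FixtureSpec(seed=1, n=8), resources_en,
                               ref_en)
    b, _ = s.generate_fixtures(s.FixtureSpec(seed=2, n=8), resources_en,
                               ref_en)
    assert [r.text for r in a] != [r.text for r in b]


def test_zero_count_yields_empty_batch(resources_en, ref_en):
    records, truths = s.generate_fixtures(s.FixtureSpec(seed=1, n=0),
                                          resources_en, ref_en)
    assert records == [] and truths == []


def test_planted_qualifiers_and_name_appear_in_text(resources_en, ref_en):
    plan = s.StatementPlan(q_target=5, overlap_fraction=0.5,
                           name_present=True)
    records, truths = s.generate_fixtures(
        s.FixtureSpec(seed=3, plans=(plan,)), resources_en, ref_en)
    (record,), (truth,) = records, truths
    assert ref_en.patient_name in record.text
    assert truth.score("sq") == 2 and truth.score("name") == 1
    stmt = s.analyze(record.text, "en", backend=resources_en.analyzer)
    assert len(s.find_semantic_qualifiers(
        stmt, resources_en.sq_lexicon)) == 5


@pytest.mark.parametrize("plan,message", [
    (s.StatementPlan(contradiction_present=True, q_target=0,
                     overlap_fraction=0.5), "q_target"),
    (s.StatementPlan(contradiction_present=True, q_target=1,
                     overlap_fraction=0.0), "overlap_fraction"),
    (s.StatementPlan(q_target=-1), "non-negative"),
])
def test_unachievable_plants_name_the_parameter(plan, message,
                                                resources_en, ref_en):
    with pytest.raises(s.FixtureError, match=message):
        s.generate_fixtures(s.FixtureSpec(seed=1, plans=(plan,)),
                            resources_en, ref_en)


def test_name_plant_requires_reference_name(resources_en):
    ref = s.VPReference(vp_id="x", language="en",
                        expert_statement="Chronic cough and fever.",
                        key_findings=("weight loss", "night sweats",
                                      "hemoptysis", "loss of appetite"),
                        final_diagnoses=("tuberculosis",))
    with pytest.raises(s.FixtureError, match="patient_name"):
        s.generate_fixtures(
            s.FixtureSpec(seed=1, plans=(s.StatementPlan(name_present=True),)),
            resources_en, ref)


def test_vocabulary_mismatch_is_detected(resources_en, ref_en):
    bad = s.fixtures.VOCAB_EN.__class__(
        **{**vars(s.fixtures.VOCAB_EN),
           "expert_term_surfaces": ("cough", "appendicitis")})
    with pytest.raises(s.FixtureError, match="appendicitis"):
        FixtureGenerator(resources_en, ref_en, vocab=bad)


def test_planted_recovery_german(resources_de, ref_de):
    records, truths = s.generate_fixtures(
        s.FixtureSpec(seed=5, n=25, language="de"), resources_de, ref_de)
    rater = s.Rater(resources_de, ref_de)
    for rec, truth in zip(records, truths):
        assert rater.rate(rec.text).scores() == truth.scores(), rec.text


# -- CLI -------------------------------------------------------------------

@pytest.fixture()
def runner():
    return CliRunner()


def test_cli_rate_writes_six_category_report(tmp_path, runner, ref_en):
    batch = tmp_path / "batch.csv"
    s.write_statements(
        [s.StatementRecord("s1", ref_en.vp_id, "en",
                           "Severe chronic cough with weight loss.")],
        batch)
    out = tmp_path / "report.json"
    ref_path = s.packaged_data_dir() / "examples" / "reference_en.yaml"
    result = runner.invoke(cli_main, [
        "rate", "--statements", str(batch), "--reference", str(ref_path),
        "--out", str(out)])
    assert result.exit_code == 0, result.output
    report = json.loads(out.read_text())
    (entry,) = report["reports"]
    assert set(entry["categories"]) == set(s.scoring.CATEGORIES)
    assert "lexicons" in entry["provenance"]


def test_cli_rate_missing_file_exits_2(tmp_path, runner):
    result = runner.invoke(cli_main, [
        "rate", "--statements", str(tmp_path / "nope.csv"),
        "--reference", str(tmp_path / "nope.yaml"),
        "--out", str(tmp_path / "r.json")])
    assert result.exit_code == 2


def test_cli_evaluate_reproduces_validated_kappa(tmp_path, runner):
    pairs = s.pairs_from_matrix(study_matrix("name"))
    path = tmp_path / "pairs.csv"
    s.write_pairs(pairs, path)
    out = tmp_path / "agreement.json"
    result = runner.invoke(cli_main, ["evaluate", "--pairs", str(path),
                                      "--out", str(out)])
    assert result.exit_code == 0, result.output
    report = json.loads(out.read_text())
    assert report["name"]["kappa"] == pytest.approx(0.783, abs=5e-4)
    assert report["name"]["matrix"] == STUDY_MATRICES["name"]


def test_cli_gen_fixtures_then_rate_recovers_plants(tmp_path, runner,
                                                    resources_en, ref_en):
    out_dir = tmp_path / "fx"
    result = runner.invoke(cli_main, [
        "gen-fixtures", "--seed", "9", "--n", "6", "--out-dir", str(out_dir)])
    assert result.exit_code == 0, result.output
    records = s.read_statements(out_dir / "fixtures.csv")
    truths = json.loads((out_dir / "ground_truth.json").read_text())
    rater = s.Rater(resources_en, ref_en)
    assert len(records) == 6
    for rec, truth in zip(records, truths):
        got = rater.rate(rec.text).scores()
        want = {c: truth["categories"][c]["score"]
                for c in got}
        assert got == want
        assert rec.manual == want  # planted scores travel as manual columns


def test_cli_analyze_dumps_structure(runner):
    result = runner.invoke(cli_main, [
        "analyze", "--text", "Cough that lasted 3 months.",
        "--language", "en"])
    assert result.exit_code == 0
    payload = json.loads(result.output)
    three = next(t for t in payload["tokens"] if t["surface"] == "3")
    assert three["dep"] == "nummod"


def test_cli_determinism_byte_identical_reports(tmp_path, runner):
    args = ["gen-fixtures", "--seed", "4", "--n", "5",
            "--format", "jsonl"]
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    assert runner.invoke(cli_main, args + ["--out-dir", str(out_a)]).exit_code == 0
    assert runner.invoke(cli_main, args + ["--out-dir", str(out_b)]).exit_code == 0
    assert (out_a / "fixtures.jsonl").read_bytes() == \
        (out_b / "fixtures.jsonl").read_bytes()
    assert (out_a / "ground_truth.json").read_bytes() == \
        (out_b / "ground_truth.json").read_bytes()
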