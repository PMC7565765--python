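"""Per-virtual-patient reference bundles and expert-side quantities.

Each virtual patient (VP) ships a reference bundle: the case author's
expert summary statement, the patient's name, and metadata lists of final
diagnoses and key findings.  From this the scorers need a derived
:class:`ExpertProfile`: the deduplicated expert term set (size ``E``), the
expert's semantic-qualifier usage with concept anchors, the expert
transformed-term count ``T_e``, and normalized patient-name variants for
the metadata name-matching route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import HONORIFICS, AnalyzedStatement, analyze, lemmatize
from .errors import ConfigurationError
from . import lexicon as lx


@dataclass(frozen=True)
class VPReference:
    """Reference bundle for one virtual patient."""
    vp_id: str
    language: str
    expert_statement: str
    patient_name: str | None = None
    final_diagnoses: tuple[str, ...] = ()
    key_findings: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.expert_statement.strip():
            raise ConfigurationError(
                f"reference {self.vp_id!r}: expert_statement must be non-empty")
        if self.language not in ("en", "de"):
            raise ConfigurationError(
                f"reference {self.vp_id!r}: unsupported language "
                f"{self.language!r}")


@dataclass(frozen=True)
class ExpertTerm:
    """One deduplicated expert-side term, keyed by (lemma sequence,
    category)."""
    lemma_key: str
    category: str
    source: str  # statement | diagnoses | findings


@dataclass(frozen=True)
class ExpertProfile:
    """Expert-side quantities for one VP.

    ``expert_terms`` is the union of classified terms from the expert
    statement and the metadata lists, deduplicated by (lemma, category);
    its size is the narrowing denominator ``E``.
    """
    vp_id: str
    language: str
    expert_terms: tuple[ExpertTerm, ...]
    expert_sq: tuple[tuple[lx.SQMatch, str | None], ...]
    expert_transformed: int
    name_forms: tuple[str, ...]
    expert_analysis: AnalyzedStatement = field(repr=False, compare=False, default=None)

    @property
    def E(self) -> int:
        return len(self.expert_terms)


def load_reference(path: str | Path) -> VPReference:
    """Load a reference bundle from a YAML or JSON file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: reference bundle must be a mapping")
    try:
        return VPReference(
            vp_id=str(data["vp_id"]),
            language=str(data["language"]),
            expert_statement=str(data["expert_statement"]),
            patient_name=(str(data["patient_name"])
                          if data.get("patient_name") else None),
            final_diagnoses=tuple(data.get("final_diagnoses") or ()),
            key_findings=tuple(data.get("key_findings") or ()),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing reference key {exc}") from exc


def _name_forms(name: str | None, language: str) -> tuple[str, ...]:
    """Given/surname/full-name variants, honorific-stripped, case-folded."""
    if not name:
        return ()
    parts = [p for p in name.split() if p.strip(".").lower() not in HONORIFICS]
    forms = {" ".join(parts).lower()} if parts else set()
    for p in parts:
        if len(p) >= 2:
            forms.add(p.lower())
    if language == "de":
        forms |= {f.replace("ß", "ss") for f in forms}
    return tuple(sorted(f for f in forms if f))


def _metadata_terms(items: tuple[str, ...], category: str, language: str,
                    thesaurus: list[lx.TermEntry]) -> list[ExpertTerm]:
    """Classify metadata phrases; a phrase absent from the thesaurus still
    becomes an expert term (its normalized lemma sequence) with the
    category implied by the list it came from."""
    source = "diagnoses" if category == "diagnosis" else "findings"
    out: list[ExpertTerm] = []
    for item in items:
        stmt = analyze(item, language)
        classified = lx.classify_terms(stmt, thesaurus)
        if classified:
            out.extend(ExpertTerm(t.lemma_key, t.category, source)
                       for t in classified)
        else:
            lemmas = [t.lemma for t in stmt.tokens if not t.is_punct]
            if lemmas:
                out.append(ExpertTerm(" ".join(lemmas), category, source))
    return out


def build_expert_profile(ref: VPReference, sq_lexicon: list[lx.SQEntry],
                         thesaurus: list[lx.TermEntry], units: set[str],
                         analyzer=None,
                         sq_context_filter: bool = True) -> ExpertProfile:
    """Analyze the expert statement and metadata into an ExpertProfile.

    The same lexicon operations used on learner statements run on the
    expert statement, so expert and learner quantities are commensurate.
    A profile with no scorable terms (E = 0) is a configuration error:
    the narrowing ratio would be undefined.
    """
    stmt = analyze(ref.expert_statement, ref.language, backend=analyzer,
                   statement_id=f"expert:{ref.vp_id}")
    classified = lx.classify_terms(stmt, thesaurus)
    terms: dict[tuple[str, str], ExpertTerm] = {}
    for t in classified:
        terms.setdefault((t.lemma_key, t.category),
                         ExpertTerm(t.lemma_key, t.category, "statement"))
    for et in _metadata_terms(ref.final_diagnoses, "diagnosis",
                              ref.language, thesaurus):
        terms.setdefault((et.lemma_key, et.category), et)
    for et in _metadata_terms(ref.key_findings, "finding",
                              ref.language, thesaurus):
        terms.setdefault((et.lemma_key, et.category), et)
    if not terms:
        raise ConfigurationError(
            f"reference {ref.vp_id!r}: expert reference yields no scorable "
            f"terms (E = 0); add thesaurus-covered terms or metadata")

    sq_matches = lx.find_semantic_qualifiers(stmt, sq_lexicon,
                                             context_filter=sq_context_filter)
    anchored = lx.attach_qualifiers(stmt, sq_matches, classified)
    t_e, _, _, _ = lx.count_transformation_evidence(stmt, thesaurus, units)

    ordered = tuple(sorted(terms.values(),
                           key=lambda t: (t.lemma_key, t.category)))
    return ExpertProfile(
        vp_id=ref.vp_id,
        language=ref.language,
        expert_terms=ordered,
        expert_sq=tuple(anchored),
        expert_transformed=t_e,
        name_forms=_name_forms(ref.patient_name, ref.language),
        expert_analysis=stmt,
    )
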