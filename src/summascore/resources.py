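"""Bundled scoring resources: lexicons, analyzer, thresholds, options.

A :class:`Resources` object carries everything the rater needs besides the
per-VP reference bundle.  :func:`load_resources` assembles one from a
lexicon directory (defaulting to the packaged vocabularies) and records
file checksums so every rating report is attributable to exact vocabulary
versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from pathlib import Path

from .analysis import get_analyzer
from . import lexicon as lx


def packaged_data_dir() -> Path:
    """Directory of the vocabularies shipped with the package."""
    return Path(importlib_resources.files("summascore") / "data")


@dataclass(frozen=True)
class RubricThresholds:
    """Score-formula thresholds of the six-category rubric.

    Counts: fewer than ``sq_low`` qualifiers scores 0, more than
    ``sq_high`` scores 2.  Ratio bounds for narrowing (``narrow_*``) and
    transformation (``transform_*``), sum bounds for the global rating,
    and the token divisor of the statement-length factor L.
    """
    sq_low: int = 2
    sq_high: int = 4
    narrow_zero: float = 0.75
    narrow_two: float = 0.25
    transform_zero: float = 0.16
    transform_two: float = 0.7
    global_zero: int = 2
    global_one: int = 5
    length_factor_divisor: int = 25

    def __post_init__(self):
        if not (0 < self.narrow_two < self.narrow_zero < 1):
            raise ValueError("require 0 < narrow_two < narrow_zero < 1")
        if not (0 < self.transform_zero < self.transform_two):
            raise ValueError("require 0 < transform_zero < transform_two")
        if not self.global_zero < self.global_one:
            raise ValueError("require global_zero < global_one")
        if self.length_factor_divisor <= 0:
            raise ValueError("length_factor_divisor must be positive")


@dataclass(frozen=True)
class ScoringOptions:
    """Behavioural switches left open by the rubric definition.

    ``sq_count_mode``: count qualifier occurrences (default) or distinct
    qualifier types.  ``sq_context_filter``: require a qualifier to modify
    or prefix a concept.  ``lenient_contradictions``: pair antonymous
    qualifiers across whole statements instead of anchoring them to a
    shared concept.  ``fuzzy_term_match``: allow near-miss lemma matching
    of expert terms (edit-ratio >= ``fuzzy_threshold``).
    """
    sq_count_mode: str = "occurrences"   # occurrences | types
    sq_context_filter: bool = True
    lenient_contradictions: bool = False
    fuzzy_term_match: bool = False
    fuzzy_threshold: float = 0.9

    def __post_init__(self):
        if self.sq_count_mode not in ("occurrences", "types"):
            raise ValueError(f"unknown sq_count_mode {self.sq_count_mode!r}")


@dataclass(frozen=True)
class Resources:
    """Everything language-level the rater consumes."""
    sq_lexicon: list[lx.SQEntry]
    thesaurus: list[lx.TermEntry]
    units: set[str]
    analyzer: object
    thresholds: RubricThresholds = field(default_factory=RubricThresholds)
    options: ScoringOptions = field(default_factory=ScoringOptions)
    provenance: dict = field(default_factory=dict)

    def with_options(self, **kwargs) -> "Resources":
        return replace(self, options=replace(self.options, **kwargs))


def load_resources(lexicon_dir: str | Path | None = None,
                   language: str = "en",
                   analyzer: str = "fallback",
                   thresholds: RubricThresholds | None = None,
                   options: ScoringOptions | None = None) -> Resources:
    """Load lexicons for one language plus the analyzer backend.

    ``lexicon_dir`` defaults to the packaged data directory and must
    contain ``sq_<lang>.tsv``, ``thesaurus_<lang>.tsv`` and
    ``si_units.tsv``.
    """
    base = Path(lexicon_dir) if lexicon_dir else packaged_data_dir()
    sq_path = base / f"sq_{language}.tsv"
    th_path = base / f"thesaurus_{language}.tsv"
    units_path = base / "si_units.tsv"
    prov = {
        "analyzer": analyzer,
        "language": language,
        "lexicons": {p.name: lx.lexicon_checksum(p)
                     for p in (sq_path, th_path, units_path)},
    }
    res = Resources(
        sq_lexicon=lx.load_sq_lexicon(sq_path),
        thesaurus=lx.load_thesaurus(th_path),
        units=lx.load_si_units(units_path),
        analyzer=get_analyzer(analyzer),
        thresholds=thresholds or RubricThresholds(),
        options=options or ScoringOptions(),
        provenance=prov,
    )
    return res
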