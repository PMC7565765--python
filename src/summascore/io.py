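"""Batch input/output: statement batches and rating-pair files.

Statement batches travel as UTF-8 CSV (RFC 4180) or JSON-lines; both
encodings carry the same records and round-trip losslessly.  Rating pairs
for agreement evaluation travel as CSV with columns
``statement_id, category, manual, automatic``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .agreement import RatingPair
from .errors import ValidationError
from .scoring import CATEGORIES

MANUAL_COLUMNS = {c: f"manual_{c}" for c in CATEGORIES}
_REQUIRED = ("statement_id", "vp_id", "language", "text")


@dataclass(frozen=True)
class StatementRecord:
    """One learner statement in a batch, optionally with manual scores."""
    statement_id: str
    vp_id: str
    language: str
    text: str
    manual: dict[str, int] = field(default_factory=dict)


def _validate_records(rows: list[dict], source: str) -> list[StatementRecord]:
    records, errors, seen = [], [], set()
    for rowno, row in rows:
        row_errors = []
        for key in _REQUIRED:
            if key not in row or row[key] is None or str(row[key]) == "":
                row_errors.append(f"{source}:row {rowno}: missing {key!r}")
        if row_errors:
            errors.extend(row_errors)
            continue
        sid = str(row["statement_id"])
        if sid in seen:
            errors.append(f"{source}:row {rowno}: duplicate statement_id "
                          f"{sid!r}")
            continue
        seen.add(sid)
        language = str(row["language"])
        if language not in ("en", "de"):
            errors.append(f"{source}:row {rowno}: unknown language "
                          f"{language!r}")
            continue
        manual = {}
        for cat, col in MANUAL_COLUMNS.items():
            val = row.get(col)
            if val is None or val == "":
                continue
            try:
                manual[cat] = int(val)
            except (TypeError, ValueError):
                errors.append(f"{source}:row {rowno}: non-integer {col}="
                              f"{val!r}")
        records.append(StatementRecord(sid, str(row["vp_id"]), language,
                                       str(row["text"]), manual))
    if errors:
        raise ValidationError(f"{len(errors)} invalid row(s) in {source}",
                              errors)
    return records


def read_statements(path: str | Path) -> list[StatementRecord]:
    """Read a statement batch from CSV or JSON-lines (by extension)."""
    path = Path(path)
    rows: list[tuple[int, dict]] = []
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with open(path, encoding="utf-8") as fh:
            for rowno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append((rowno, json.loads(line)))
                except json.JSONDecodeError as exc:
                    raise ValidationError(
                        f"{path}:row {rowno}: invalid JSON ({exc})") from exc
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ValidationError(f"{path}: empty file")
            for rowno, row in enumerate(reader, start=2):
                rows.append((rowno, row))
    return _validate_records(rows, str(path))


def write_statements(records: list[StatementRecord], path: str | Path) -> None:
    """Write a batch in the format implied by the extension."""
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                row = {"statement_id": rec.statement_id, "vp_id": rec.vp_id,
                       "language": rec.language, "text": rec.text}
                for cat, col in MANUAL_COLUMNS.items():
                    if cat in rec.manual:
                        row[col] = rec.manual[cat]
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
        return
    fieldnames = list(_REQUIRED) + list(MANUAL_COLUMNS.values())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for rec in records:
            row = {"statement_id": rec.statement_id, "vp_id": rec.vp_id,
                   "language": rec.language, "text": rec.text}
            for cat, col in MANUAL_COLUMNS.items():
                if cat in rec.manual:
                    row[col] = rec.manual[cat]
            writer.writerow(row)


def read_pairs(path: str | Path) -> list[RatingPair]:
    """Read rating pairs (statement_id, category, manual, automatic)."""
    pairs, errors = [], []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for rowno, row in enumerate(reader, start=2):
            try:
                pairs.append(RatingPair(
                    statement_id=str(row["statement_id"]),
                    category=str(row["category"]),
                    manual=int(row["manual"]),
                    automatic=int(row["automatic"])))
            except (KeyError, TypeError, ValueError) as exc:
                errors.append(f"{path}:row {rowno}: {exc!r}")
    if errors:
        raise ValidationError(f"{len(errors)} invalid pair row(s)", errors)
    return pairs


def write_pairs(pairs: list[RatingPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["statement_id", "category", "manual", "automatic"])
        for p in pairs:
            writer.writerow([p.statement_id, p.category, p.manual,
                             p.automatic])
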