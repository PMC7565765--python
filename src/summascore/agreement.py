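"""Manual-vs-automatic agreement statistics.

Cross-tabulates ordinal rating pairs per rubric category (automatic rating
on rows, manual rating on columns), and computes percent agreement and
unweighted Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = trace / total,   p_e = sum_k row_k * col_k / total**2,

with interpretation bands: <= 0.20 none/slight, 0.21-0.40 fair, 0.41-0.60
moderate, 0.61-0.80 substantial, 0.81-1.00 almost perfect.  The full label
range of a category is always present in the marginals even when a label
is unobserved, fixing the matrix shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .scoring import CATEGORY_RANGES

KAPPA_BANDS = (
    (0.20, "none/slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def category_labels(category: str) -> list[int]:
    lo, hi = CATEGORY_RANGES.get(category, (0, 2))
    return list(range(lo, hi + 1))


@dataclass(frozen=True)
class RatingPair:
    """One statement's (manual, automatic) score pair in one category."""
    statement_id: str
    category: str
    manual: int
    automatic: int


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cross-tabulation with automatic scores on rows, manual on columns."""
    category: str
    labels: tuple[int, ...]
    counts: tuple[tuple[int, ...], ...]

    @property
    def total(self) -> int:
        return int(sum(sum(row) for row in self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class AgreementStats:
    """Percent agreement, Cohen's kappa and its interpretation band.

    ``kappa`` is NaN (band "undefined") when chance agreement is 1, i.e.
    both raters are constant on the same single label.
    """
    percent_agreement: float
    kappa: float
    band: str


def kappa_band(kappa: float) -> str:
    if math.isnan(kappa):
        return "undefined"
    if kappa <= 0.0:
        return "none/slight"
    for upper, name in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return name
    return "almost perfect"


def build_confusion(pairs: list[RatingPair], category: str) -> ConfusionMatrix:
    """Tally pairs of one category into a full-label-range matrix."""
    labels = category_labels(category)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    errors = []
    for p in pairs:
        if p.category != category:
            errors.append(f"{p.statement_id}: category {p.category!r} != "
                          f"{category!r}")
            continue
        if p.automatic not in index or p.manual not in index:
            errors.append(
                f"{p.statement_id}: score outside range {labels} "
                f"(automatic={p.automatic}, manual={p.manual})")
            continue
        counts[index[p.automatic], index[p.manual]] += 1
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid rating pair(s) for {category!r}", errors)
    return ConfusionMatrix(category, tuple(labels),
                           tuple(tuple(int(c) for c in row) for row in counts))


def percent_agreement(m: ConfusionMatrix) -> float:
    """Congruent rating: 100 x (diagonal sum / total)."""
    a = m.as_array()
    total = a.sum()
    if total == 0:
        raise ValidationError("percent agreement undefined for empty matrix")
    return 100.0 * float(np.trace(a)) / float(total)


def cohen_kappa(m: ConfusionMatrix) -> AgreementStats:
    """Unweighted Cohen's kappa with interpretation band."""
    a = m.as_array().astype(float)
    total = a.sum()
    if total == 0:
        raise ValidationError("kappa undefined for empty matrix")
    p_o = np.trace(a) / total
    p_e = float((a.sum(axis=1) * a.sum(axis=0)).sum()) / total**2
    if abs(1.0 - p_e) < 1e-12:
        kappa = math.nan  # degenerate single-cell marginals
    else:
        kappa = float((p_o - p_e) / (1.0 - p_e))
    return AgreementStats(percent_agreement=100.0 * float(p_o), kappa=kappa,
                          band=kappa_band(kappa))


def pairs_from_matrix(m: ConfusionMatrix) -> list[RatingPair]:
    """Expand a printed confusion matrix back into rating pairs."""
    pairs = []
    k = 0
    for i, auto in enumerate(m.labels):
        for j, manual in enumerate(m.labels):
            for _ in range(m.counts[i][j]):
                pairs.append(RatingPair(f"{m.category}-{k:04d}", m.category,
                                        manual=manual, automatic=auto))
                k += 1
    return pairs


def agreement_report(pairs: list[RatingPair]) -> dict:
    """Per-category agreement report (machine-readable form).

    One entry per category present in the pairs: confusion matrix, percent
    agreement, kappa and band.  Order-invariant in the input pairs.
    """
    by_cat: dict[str, list[RatingPair]] = {}
    for p in pairs:
        by_cat.setdefault(p.category, []).append(p)
    report = {}
    for category in sorted(by_cat):
        m = build_confusion(by_cat[category], category)
        stats = cohen_kappa(m)
        report[category] = {
            "n": m.total,
            "labels": list(m.labels),
            "matrix": [list(row) for row in m.counts],
            "percent_agreement": stats.percent_agreement,
            "kappa": stats.kappa,
            "band": stats.band,
        }
    return report


def render_report(report: dict) -> str:
    """Aligned-text rendering of an agreement report."""
    lines = []
    header = (f"{'category':<16} {'n':>5} {'agree%':>8} {'kappa':>8} band")
    lines.append(header)
    lines.append("-" * len(header))
    for category, entry in report.items():
        kap = entry["kappa"]
        kap_s = "   nan" if isinstance(kap, float) and math.isnan(kap) \
            else f"{kap:8.3f}"
        lines.append(f"{category:<16} {entry['n']:>5} "
                     f"{entry['percent_agreement']:8.1f} {kap_s:>8} "
                     f"{entry['band']}")
        for lab, row in zip(entry["labels"], entry["matrix"]):
            cells = " ".join(f"{c:>5}" for c in row)
            lines.append(f"    auto={lab}  {cells}")
    return "\n".join(lines)
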