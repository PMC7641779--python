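"""Entity-level evaluation: exact span+label matching, micro and per-label P/R/F1.

A predicted span counts as a true positive iff a gold span with the
identical (section, start, end, label) exists in the same document,
matched one-to-one; unmatched predictions are false positives and
unmatched gold spans false negatives. Micro-averaging pools TP/FP/FN over
all labels before computing precision/recall/F1. Percentages are rounded
half-up to two decimals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from pgxkit.corpus import ENTITY_LABELS, SpanAnnotation

__all__ = ["EvalReport", "prf", "evaluate", "evaluate_counts", "report_to_tsv"]

#: Granularity declared in every report header.
GRANULARITY = "entity-level (exact span + label match)"


def _pct(x: float) -> float:
    """Percentage rounded half-up to 2 decimals."""
    return float(Decimal(repr(100.0 * x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(precision %, recall %, F1 %) from pooled counts.

    F1 is the harmonic mean of precision and recall, 0 when both are 0.
    """
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return _pct(p), _pct(r), _pct(f)


@dataclass
class EvalReport:
    """Per-label and micro-averaged precision/recall/F1 with raw counts."""

    per_label: dict[str, tuple[float, float, float]]
    micro: tuple[float, float, float]
    counts: dict[str, tuple[int, int, int]]  # label -> (TP, FP, FN)
    granularity: str = GRANULARITY


def evaluate_counts(counts: Mapping[str, tuple[int, int, int]]) -> EvalReport:
    """Build a report directly from per-label (TP, FP, FN) counts."""
    per_label = {lab: prf(*c) for lab, c in counts.items()}
    tp = sum(c[0] for c in counts.values())
    fp = sum(c[1] for c in counts.values())
    fn = sum(c[2] for c in counts.values())
    return EvalReport(per_label=per_label, micro=prf(tp, fp, fn), counts=dict(counts))


def evaluate(
    gold: Mapping[str, Sequence[SpanAnnotation]],
    pred: Mapping[str, Sequence[SpanAnnotation]],
    labels: Iterable[str] = ENTITY_LABELS,
) -> EvalReport:
    """Score predicted spans against gold spans, keyed by document id."""
    if set(gold) != set(pred):
        raise ValueError("gold and predicted annotations must cover the same documents")
    counts: dict[str, list[int]] = {lab: [0, 0, 0] for lab in labels}
    for doc_id in gold:
        g = Counter(s.key() for s in gold[doc_id])
        p = Counter(s.key() for s in pred[doc_id])
        for key, n in p.items():
            label = key[3]
            counts.setdefault(label, [0, 0, 0])
            matched = min(n, g.get(key, 0))
            counts[label][0] += matched
            counts[label][1] += n - matched
        for key, n in g.items():
            label = key[3]
            counts.setdefault(label, [0, 0, 0])
            counts[label][2] += n - min(n, p.get(key, 0))
    return evaluate_counts({lab: tuple(c) for lab, c in counts.items()})


def report_to_tsv(report: EvalReport) -> str:
    """Serialize a report to a TSV table (header declares the granularity)."""
    lines = [f"# granularity: {report.granularity}"]
    lines.append("label\tprecision\trecall\tf1\ttp\tfp\tfn")
    for lab in sorted(report.per_label):
        p, r, f = report.per_label[lab]
        tp, fp, fn = report.counts.get(lab, (0, 0, 0))
        lines.append(f"{lab}\t{p:.2f}\t{r:.2f}\t{f:.2f}\t{tp}\t{fp}\t{fn}")
    p, r, f = report.micro
    lines.append(f"micro\t{p:.2f}\t{r:.2f}\t{f:.2f}\t\t\t")
    return "\n".join(lines) + "\n"
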