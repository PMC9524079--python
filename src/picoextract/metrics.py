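"""Entity-level evaluation: per-document precision/recall/F1, macro-averaged.

A predicted entity is *correct* only when its (type, start, end) triple
exactly matches a gold entity; boundary mismatches count as errors.  Metrics
are computed per document,

    precision_i = correct_i / predicted_i
    recall_i    = correct_i / gold_i
    F1_i        = 2 * precision_i * recall_i / (precision_i + recall_i),

then arithmetically averaged across documents (macro averaging — not pooled
corpus counts).  Per-type averages skip documents where the type occurs in
neither gold nor prediction.

Zero conventions: no predictions against non-empty gold scores 0 across the
board; a document with neither gold nor predicted entities (for the span set
under evaluation) is excluded from the average.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .corpus import Document, EntitySpan, EntityType


@dataclass
class MetricResult:
    precision: float
    recall: float
    f1: float
    n_pred: int
    n_gold: int
    n_correct: int

    @property
    def defined(self) -> bool:
        """False when the document had neither gold nor predicted entities."""
        return self.n_pred > 0 or self.n_gold > 0


def _overlap_correct(pred: list[EntitySpan], gold: list[EntitySpan]) -> int:
    matched: set[int] = set()
    hits = 0
    for p in pred:
        for gi, g in enumerate(gold):
            if gi in matched or g.type is not p.type:
                continue
            if p.start < g.end and g.start < p.end:
                matched.add(gi)
                hits += 1
                break
    return hits


def entity_prf(
    pred: list[EntitySpan], gold: list[EntitySpan], *, overlap: bool = False,
) -> MetricResult:
    """Exact-match entity precision/recall/F1 for one document.

    ``overlap=True`` switches to a diagnostic mode where same-type partial
    overlaps count as hits; headline numbers always use exact matching.
    """
    n_pred, n_gold = len(pred), len(gold)
    if overlap:
        n_correct = _overlap_correct(pred, gold)
    else:
        pred_keys = Counter(s.key for s in pred)
        gold_keys = Counter(s.key for s in gold)
        n_correct = sum((pred_keys & gold_keys).values())
    if n_pred == 0 and n_gold == 0:
        return MetricResult(0.0, 0.0, 0.0, 0, 0, 0)
    precision = n_correct / n_pred if n_pred else 0.0
    recall = n_correct / n_gold if n_gold else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MetricResult(precision, recall, f1, n_pred, n_gold, n_correct)


def per_type_prf(
    pred: list[EntitySpan], gold: list[EntitySpan], etype: EntityType,
    *, overlap: bool = False,
) -> MetricResult:
    """``entity_prf`` restricted to spans of one entity type."""
    return entity_prf([s for s in pred if s.type is etype],
                      [s for s in gold if s.type is etype], overlap=overlap)


def _mean(values: list[float]) -> float:
    return sum(values) / len(values)


@dataclass
class AggregateReport:
    overall: MetricResult
    per_type: dict[EntityType, MetricResult]
    n_documents: int


def aggregate(per_doc: list[MetricResult]) -> AggregateReport:
    """Macro-average per-document results (overall only; no type breakdown)."""
    if not per_doc:
        raise ValueError("cannot aggregate an empty result list")
    used = [r for r in per_doc if r.defined]
    if not used:
        raise ValueError("all documents are empty for this span set")
    overall = MetricResult(
        precision=_mean([r.precision for r in used]),
        recall=_mean([r.recall for r in used]),
        f1=_mean([r.f1 for r in used]),
        n_pred=sum(r.n_pred for r in used),
        n_gold=sum(r.n_gold for r in used),
        n_correct=sum(r.n_correct for r in used),
    )
    return AggregateReport(overall=overall, per_type={}, n_documents=len(used))


def evaluate_documents(
    docs: list[Document], *, overlap: bool = False,
    count_missing_types_as_zero: bool = False,
) -> AggregateReport:
    """Score ``pred_spans`` against ``gold_spans`` across a corpus.

    Overall metrics are macro averages of per-document results; per-type
    averages are taken over documents where the type appears in gold or
    prediction (``count_missing_types_as_zero=True`` averages over all
    documents instead).
    """
    if not docs:
        raise ValueError("cannot evaluate an empty corpus")
    per_doc = [entity_prf(d.pred_spans, d.gold_spans, overlap=overlap)
               for d in docs]
    report = aggregate(per_doc)
    for etype in EntityType:
        results = [per_type_prf(d.pred_spans, d.gold_spans, etype,
                                overlap=overlap) for d in docs]
        if not count_missing_types_as_zero:
            results = [r for r in results if r.defined]
        if not results:
            continue
        report.per_type[etype] = MetricResult(
            precision=_mean([r.precision for r in results]),
            recall=_mean([r.recall for r in results]),
            f1=_mean([r.f1 for r in results]),
            n_pred=sum(r.n_pred for r in results),
            n_gold=sum(r.n_gold for r in results),
            n_correct=sum(r.n_correct for r in results),
        )
    return report


def format_report(report: AggregateReport) -> str:
    """Plain-text table: one row per entity type plus the overall row."""
    lines = [f"{'':14s}{'F1':>8s}{'Recall':>8s}{'Precision':>10s}{'Gold':>6s}"]
    for etype, r in report.per_type.items():
        lines.append(f"{etype.value:14s}{r.f1:8.3f}{r.recall:8.3f}"
                     f"{r.precision:10.3f}{r.n_gold:6d}")
    o = report.overall
    lines.append(f"{'Overall':14s}{o.f1:8.3f}{o.recall:8.3f}"
                 f"{o.precision:10.3f}{o.n_gold:6d}")
    lines.append(f"(macro average over {report.n_documents} documents)")
    return "\n".join(lines)
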