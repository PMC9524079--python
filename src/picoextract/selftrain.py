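"""Confidence-thresholded self-training for the entity recogniser.

The loop starts from a recogniser trained on the gold set, predicts the
unlabelled ("silver") pool, scores each silver abstract by the mean
posterior probability of its predicted tags, and accepts abstracts whose
mean confidence is strictly greater than the threshold (0.95 or 0.99 in the
published experiments).  Accepted records keep their pseudo-labels, are
split 80/20 into training/validation additions, and a freshly initialised
recogniser is trained on the enlarged sets.  Iteration stops at the first
empty acceptance or after ``max_iterations`` (default 15) rounds.

Split discipline: the original gold validation documents are only ever used
for validation, and the gold test set is touched exactly once, to evaluate
the best-across-iterations model at the end.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

from . import metrics
from .corpus import Document, with_pred_as_gold
from .ner import NERConfig, NERModel, predict_spans, train_ner


@dataclass
class SelfTrainConfig:
    threshold: float = 0.95          # acceptance threshold on mean confidence
    max_iterations: int = 15
    silver_split: tuple[float, float] = (0.8, 0.2)  # train/val shares
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        if abs(sum(self.silver_split) - 1.0) > 1e-9:
            raise ValueError("silver_split must sum to 1")


@dataclass
class IterationRecord:
    iteration: int
    accepted_ids: list[str]
    n_train: int
    n_val: int
    val_f1: float


@dataclass
class SelfTrainHistory:
    iterations: list[IterationRecord] = field(default_factory=list)
    best_iteration: int = 0
    test_f1: float | None = None  # filled once, from the final evaluation


def doc_confidence(token_confidences: list[float]) -> float:
    """Mean per-token confidence of one document's prediction."""
    if not token_confidences:
        raise ValueError("cannot average an empty confidence list")
    if any(c < 0.0 or c > 1.0 for c in token_confidences):
        raise ValueError("confidences must lie in [0, 1]")
    return sum(token_confidences) / len(token_confidences)


def select_silver(
    predicted: list[tuple[Document, float]], threshold: float,
) -> list[Document]:
    """Documents with confidence strictly greater than *threshold*.

    Selected documents carry their predicted spans as pseudo-gold.
    """
    return [with_pred_as_gold(doc) for doc, conf in predicted if conf > threshold]


def _split_80_20(docs: list[Document], shares: tuple[float, float],
                 seed: int) -> tuple[list[Document], list[Document]]:
    """Floor the validation share; remainder goes to training (10 -> 8/2)."""
    ordered = sorted(docs, key=lambda d: d.doc_id)
    random.Random(seed).shuffle(ordered)
    n_val = int(len(ordered) * shares[1])
    return ordered[n_val:], ordered[:n_val]


def _gold_val_f1(model: NERModel, docs: list[Document]) -> float:
    scored = []
    for doc in docs:
        spans, _, _ = predict_spans(model, doc)
        scored.append(metrics.entity_prf(spans, doc.gold_spans))
    return metrics.aggregate(scored).overall.f1


def self_train_loop(
    gold_train: list[Document],
    gold_val: list[Document],
    gold_test: list[Document],
    silver: list[Document],
    base_config: NERConfig,
    st_config: SelfTrainConfig,
) -> tuple[NERModel, SelfTrainHistory]:
    """Run the self-training loop and return (best model, history).

    Every round retrains a freshly initialised recogniser (no warm start).
    An accepted silver record keeps the pseudo-labels from its acceptance
    round and leaves the pool — it is consumed once and never re-labelled.
    The returned model is the one with the best gold-validation overall F1
    across rounds; its gold-test F1 is recorded in the history.
    """
    gold_val_ids = {d.doc_id for d in gold_val}
    if gold_val_ids & {d.doc_id for d in gold_train}:
        raise ValueError("gold train and validation sets share documents")
    gold_ids = gold_val_ids | {d.doc_id for d in gold_train} | \
        {d.doc_id for d in gold_test}
    silver_ids = {d.doc_id for d in silver}
    if gold_ids & silver_ids:
        raise ValueError("gold and silver pools share document ids")
    if not silver:
        warnings.warn("empty silver pool: degenerate run equals plain training")

    pool = [d for d in silver if d.tokens]
    train_docs = list(gold_train)
    val_docs = list(gold_val)
    history = SelfTrainHistory()

    def fit(iteration: int) -> NERModel:
        cfg_seed = base_config.seed + iteration
        cfg = NERConfig(**{**base_config.__dict__, "seed": cfg_seed})
        return train_ner(train_docs, val_docs, cfg)

    model = fit(0)
    f1 = _gold_val_f1(model, gold_val)
    history.iterations.append(IterationRecord(
        0, [], len(train_docs), len(val_docs), f1))
    best_model, best_f1, best_iter = model, f1, 0

    for iteration in range(1, st_config.max_iterations + 1):
        if not pool:
            break
        predicted = []
        for doc in pool:
            spans, _, conf = predict_spans(model, doc)
            doc.pred_spans = spans
            predicted.append((doc, doc_confidence(conf)))
        accepted = select_silver(predicted, st_config.threshold)
        if not accepted:
            # record the empty acceptance round so the halt is auditable
            history.iterations.append(IterationRecord(
                iteration, [], len(train_docs), len(val_docs), f1))
            break
        accepted_ids = {d.doc_id for d in accepted}
        pool = [d for d in pool if d.doc_id not in accepted_ids]
        add_train, add_val = _split_80_20(
            accepted, st_config.silver_split, st_config.seed + iteration)
        assert not (accepted_ids & gold_val_ids)
        train_docs.extend(add_train)
        val_docs.extend(add_val)
        model = fit(iteration)
        f1 = _gold_val_f1(model, gold_val)
        history.iterations.append(IterationRecord(
            iteration, sorted(accepted_ids), len(train_docs), len(val_docs), f1))
        if f1 > best_f1:
            best_model, best_f1, best_iter = model, f1, iteration

    history.best_iteration = best_iter
    if gold_test:
        history.test_f1 = _gold_val_f1(best_model, gold_test)
    return best_model, history
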