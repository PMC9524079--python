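"""Stage 1: PICO sentence classification and abstract truncation.

A sentence is a *PICO sentence* iff it contains at least one annotated PICO
entity; the classifier is trained on that binary signal and, at prediction
time, non-PICO sentences are removed before entity recognition so the tagger
only ever sees PICO-bearing text.

The trainable encoder here ("baseline") averages trainable word embeddings,
passes them through one tanh hidden layer and a 2-way softmax.  It trains in
seconds on a CPU while honouring the same training contract as any larger
encoder: cross-entropy loss, AdamW, slanted-triangular or constant schedule,
global-norm gradient clipping and gradient accumulation, with checkpoint
selection by validation F1 of the positive class.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import _nn
from .corpus import Document, EntitySpan, Sentence, Token, tokenize_words

#: Supported sentence encoders. Checkpoint-style names would slot in here;
#: the package ships the self-contained baseline encoder.
ENCODER_REGISTRY = ("baseline",)


@dataclass
class SentenceExample:
    text: str
    label: bool
    prob: float | None = None


@dataclass
class ClassifierConfig:
    """Sentence-classifier training configuration.

    Defaults are the published fine-tuning regime: peak learning rate 5e-5
    for 10 epochs, gradient clipping at norm 0.1, gradient accumulation every
    16 mini-batches, slanted-triangular schedule.  ``baseline_preset`` raises
    the learning rate to a value suited to training the small baseline
    encoder from scratch (5e-5 is a fine-tuning rate).
    """

    encoder_name: str = "baseline"
    max_lr: float = 5e-5
    epochs: int = 10
    clip_norm: float = 0.1
    accumulation_steps: int = 16
    scheduler: str = "slanted_triangular"  # or "constant"
    seed: int = 0
    batch_size: int = 16
    embedding_dim: int = 32
    hidden_dim: int = 32
    weight_decay: float = 0.01

    @classmethod
    def baseline_preset(cls, seed: int = 0, **overrides) -> "ClassifierConfig":
        defaults = dict(max_lr=0.1, clip_norm=1.0, accumulation_steps=1, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


def label_pico_sentences(doc: Document) -> list[SentenceExample]:
    """One example per sentence; label true iff a gold span intersects it."""
    examples = []
    for sent in doc.sentences:
        has_entity = any(
            span.start < sent.end and sent.start < span.end
            for span in doc.gold_spans
        )
        examples.append(SentenceExample(doc.sentence_text(sent), has_entity))
    return examples


def _binary_f1(y_true: list[bool], y_pred: list[bool]) -> float:
    tp = sum(1 for t, p in zip(y_true, y_pred) if t and p)
    fp = sum(1 for t, p in zip(y_true, y_pred) if not t and p)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t and not p)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


class SentenceModel:
    """Baseline bag-of-embeddings sentence classifier."""

    def __init__(self, vocab: dict[str, int], config: ClassifierConfig) -> None:
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h = config.embedding_dim, config.hidden_dim
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0.0, 0.1, size=(len(vocab), d)),
            "W1": _nn._glorot(rng, d, h), "b1": np.zeros(h),
            "W2": _nn._glorot(rng, h, 2), "b2": np.zeros(2),
        }
        self.run_log: dict = {}

    # -- forward/backward ---------------------------------------------------
    def _ids(self, text: str) -> np.ndarray:
        return _nn.lookup_ids([t.text for t in tokenize_words(text)], self.vocab)

    def _forward(self, ids_batch: list[np.ndarray]):
        p = self.params
        x = np.stack([
            p["E"][ids].mean(axis=0) if len(ids) else np.zeros(p["E"].shape[1])
            for ids in ids_batch
        ])
        a1 = np.tanh(x @ p["W1"] + p["b1"])
        logits = a1 @ p["W2"] + p["b2"]
        return x, a1, logits

    def loss_and_grads(self, ids_batch: list[np.ndarray], labels: np.ndarray):
        p = self.params
        x, a1, logits = self._forward(ids_batch)
        loss, d_logits = _nn.softmax_xent(logits, labels)
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["W2"] = a1.T @ d_logits
        grads["b2"] = d_logits.sum(axis=0)
        d_a1 = d_logits @ p["W2"].T
        d_z1 = d_a1 * (1.0 - a1 ** 2)
        grads["W1"] = x.T @ d_z1
        grads["b1"] = d_z1.sum(axis=0)
        d_x = d_z1 @ p["W1"].T
        for row, ids in enumerate(ids_batch):
            if len(ids):
                np.add.at(grads["E"], ids, d_x[row] / len(ids))
        return loss, grads

    def predict_proba(self, sentences: list[str]) -> np.ndarray:
        """P(PICO sentence) for each input sentence."""
        if not sentences:
            return np.zeros(0)
        ids_batch = [self._ids(s) for s in sentences]
        _, _, logits = self._forward(ids_batch)
        return _nn.softmax(logits, axis=1)[:, 1]

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "sentence_model.json").write_text(json.dumps({
            "vocab": self.vocab,
            "config": asdict(self.config),
            "run_log": self.run_log,
        }))
        np.savez(path / "sentence_weights.npz", **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SentenceModel":
        path = Path(path)
        meta = json.loads((path / "sentence_model.json").read_text())
        model = cls(meta["vocab"], ClassifierConfig(**meta["config"]))
        with np.load(path / "sentence_weights.npz") as data:
            model.params = {k: data[k] for k in data.files}
        model.run_log = meta.get("run_log", {})
        return model


def train_sentence_classifier(
    train: list[SentenceExample],
    val: list[SentenceExample],
    config: ClassifierConfig,
) -> SentenceModel:
    """Train the sentence classifier and return the best-validation checkpoint.

    Selection is by validation F1 of the positive (PICO) class across epochs;
    with an empty validation set the final-epoch weights are returned with a
    warning.  Fully deterministic under ``config.seed``.
    """
    if config.encoder_name not in ENCODER_REGISTRY:
        raise ValueError(
            f"unknown encoder {config.encoder_name!r}; available: {ENCODER_REGISTRY}")
    if not train:
        raise ValueError("empty training set")
    labels_present = {ex.label for ex in train}
    if len(labels_present) < 2:
        raise ValueError("training data contains a single class")

    vocab = _nn.build_vocab(
        tok.text for ex in train for tok in tokenize_words(ex.text))
    model = SentenceModel(vocab, config)
    ids_all = [model._ids(ex.text) for ex in train]
    y_all = np.array([int(ex.label) for ex in train])

    rng = np.random.default_rng(config.seed + 1)
    n = len(train)
    batches_per_epoch = max(1, (n + config.batch_size - 1) // config.batch_size)
    updates_total = max(
        1, config.epochs * batches_per_epoch // config.accumulation_steps)
    optimizer = _nn.AdamOptimizer(model.params, lr=config.max_lr,
                                  weight_decay=config.weight_decay,
                                  decoupled_weight_decay=True)

    best: tuple[float, int, dict] | None = None
    history: list[dict] = []
    update = 0
    acc_grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    acc_count = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(batches_per_epoch):
            sel = order[b * config.batch_size:(b + 1) * config.batch_size]
            if len(sel) == 0:
                continue
            loss, grads = model.loss_and_grads(
                [ids_all[i] for i in sel], y_all[sel])
            epoch_loss += loss * len(sel)
            for k in acc_grads:
                acc_grads[k] += grads[k]
            acc_count += 1
            if acc_count == config.accumulation_steps or b == batches_per_epoch - 1:
                for k in acc_grads:
                    acc_grads[k] /= acc_count
                _nn.clip_global_norm(acc_grads, config.clip_norm)
                scale = (_nn.slanted_triangular(update, updates_total)
                         if config.scheduler == "slanted_triangular" else 1.0)
                optimizer.step(acc_grads, lr_scale=scale)
                update += 1
                acc_grads = {k: np.zeros_like(v) for k, v in model.params.items()}
                acc_count = 0
        record = {"epoch": epoch, "train_loss": epoch_loss / n}
        if val:
            probs = model.predict_proba([ex.text for ex in val])
            preds = [bool(p >= 0.5) for p in probs]
            f1 = _binary_f1([ex.label for ex in val], preds)
            record["val_f1"] = f1
            if best is None or f1 > best[0]:
                best = (f1, epoch, copy.deepcopy(model.params))
        history.append(record)

    if val and best is not None:
        model.params = best[2]
        best_epoch, best_f1 = best[1], best[0]
    else:
        if not val:
            warnings.warn("empty validation set: keeping final-epoch checkpoint")
        best_epoch, best_f1 = config.epochs - 1, float("nan")
    model.run_log = {
        "max_lr": config.max_lr, "epochs": config.epochs,
        "clip_norm": config.clip_norm,
        "accumulation_steps": config.accumulation_steps,
        "scheduler": config.scheduler, "seed": config.seed,
        "encoder_name": config.encoder_name,
        "best_epoch": best_epoch, "best_val_f1": best_f1,
        "history": history,
    }
    return model


def classify_sentences(
    model: SentenceModel, sentences: list[str],
) -> list[tuple[bool, float]]:
    """(label, probability) per sentence; label = prob >= 0.5.

    Empty/whitespace sentences are labelled false with probability 0.
    """
    out: list[tuple[bool, float]] = []
    nonempty = [i for i, s in enumerate(sentences) if s.strip()]
    if len(nonempty) < len(sentences):
        warnings.warn("empty sentence(s) labelled false with probability 0")
    probs = model.predict_proba([sentences[i] for i in nonempty])
    probmap = dict(zip(nonempty, probs))
    for i in range(len(sentences)):
        p = float(probmap.get(i, 0.0))
        out.append((p >= 0.5 if i in probmap else False, p))
    return out


@dataclass
class Truncation:
    """Result of removing non-PICO sentences from a document.

    ``offset_map`` pairs each kept sentence's new character start with its
    original start, so extracted spans can be mapped back to the source text.
    """

    document: Document
    kept_sentences: list[int]
    offset_map: list[tuple[int, int, int]]  # (new_start, orig_start, length)
    no_pico: bool = False

    def to_original(self, start: int, end: int) -> tuple[int, int]:
        """Map a [start, end) range in the truncated text back to the original."""
        for new_start, orig_start, length in self.offset_map:
            if new_start <= start and end <= new_start + length:
                delta = orig_start - new_start
                return start + delta, end + delta
        raise ValueError(f"range [{start},{end}) crosses kept-sentence boundaries")


def truncate_to_pico(doc: Document, labels: list[bool]) -> Truncation:
    """Keep only true-labelled sentences, re-basing offsets.

    Gold spans inside kept sentences are remapped (surfaces preserved
    verbatim); a span crossing sentence boundaries cannot be re-based safely
    and is dropped with a warning.  With no true labels the result is an
    empty document and the ``no_pico`` flag.
    """
    if len(labels) != len(doc.sentences):
        raise ValueError(f"{len(labels)} labels for {len(doc.sentences)} sentences")
    kept = [i for i, keep in enumerate(labels) if keep]
    if not kept:
        empty = Document(doc_id=doc.doc_id, text="", tokens=[], sentences=[])
        return Truncation(empty, [], [], no_pico=True)

    pieces: list[str] = []
    tokens: list[Token] = []
    sentences: list[Sentence] = []
    offset_map: list[tuple[int, int, int]] = []
    gold: list[EntitySpan] = []
    cursor = 0
    for new_index, si in enumerate(kept):
        sent = doc.sentences[si]
        piece = doc.sentence_text(sent)
        delta = cursor - sent.start
        token_start = len(tokens)
        for tok in doc.sentence_tokens(sent):
            tokens.append(Token(tok.text, tok.start + delta, tok.end + delta))
        sentences.append(Sentence(
            index=new_index, start=cursor, end=cursor + len(piece),
            token_start=token_start, token_end=len(tokens),
            is_pico=True,
        ))
        offset_map.append((cursor, sent.start, len(piece)))
        for span in doc.gold_spans:
            if sent.start <= span.start and span.end <= sent.end:
                gold.append(EntitySpan(span.start + delta, span.end + delta,
                                       span.type, span.text))
        pieces.append(piece)
        cursor += len(piece) + 1
    kept_ranges = [(doc.sentences[si].start, doc.sentences[si].end) for si in kept]
    for span in doc.gold_spans:
        inside = any(lo <= span.start and span.end <= hi for lo, hi in kept_ranges)
        intersects = any(span.start < hi and lo < span.end for lo, hi in kept_ranges)
        if intersects and not inside:
            warnings.warn(
                f"span [{span.start},{span.end}) crosses a sentence boundary "
                f"and was dropped during truncation")
    new_doc = Document(doc_id=doc.doc_id, text=" ".join(pieces), tokens=tokens,
                       sentences=sentences, gold_spans=sorted(gold))
    return Truncation(new_doc, kept, offset_map)
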