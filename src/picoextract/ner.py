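"""Stage 2: PICO entity recognition over the 13-tag BIO space.

Architectures compose a token encoder with a tag head:

* ``recurrent`` — trainable word embeddings into a bidirectional tanh
  recurrent layer, per-token softmax over the 13 tags;
* ``recurrent+crf`` — the same encoder with a linear-chain CRF head that
  learns tag-transition scores and decodes with Viterbi under hard BIO
  constraints;
* ``transformer`` / ``transformer+crf`` — a compact single-head
  self-attention encoder with learned positions in place of the recurrence;
* ``transformer+recurrent+crf`` — attention feeding the recurrent layer,
  CRF on top.

Softmax heads decode by per-token argmax (stray ``I-`` tags are repaired
when converting to spans); CRF heads decode with constrained Viterbi, so
their output is BIO-valid by construction.  Per-token confidences are the
posterior probability of the emitted tag — softmax posterior for softmax
heads, forward-backward marginal for CRF heads.

Presets carry the published training regimes (learning rate / epochs):
recurrent 1e-3/20, recurrent+crf 5e-3/20, transformer 1e-3/20,
transformer+crf 1e-4/30, transformer+recurrent+crf 1e-4/60.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import _nn, crf as crf_mod, metrics
from .corpus import (
    Document, TAG_VOCAB, TAG_TO_INDEX, bio_to_spans, spans_to_bio,
)

ARCHITECTURES = (
    "recurrent", "recurrent+crf", "transformer", "transformer+crf",
    "transformer+recurrent+crf",
)

#: Published training regimes per architecture.
PRESETS: dict[str, dict] = {
    "recurrent": {"lr": 1e-3, "epochs": 20},
    "recurrent+crf": {"lr": 5e-3, "epochs": 20},
    "transformer": {"lr": 1e-3, "epochs": 20},
    "transformer+crf": {"lr": 1e-4, "epochs": 30},
    "transformer+recurrent+crf": {"lr": 1e-4, "epochs": 60},
}


@dataclass
class NERConfig:
    architecture: str = "recurrent+crf"
    hidden_dim: int = 128
    embedding_dim: int = 200
    freeze_embeddings: bool = True
    lr: float = 5e-3
    epochs: int = 20
    optimizer: str = "adam"  # or "adamw"
    scheduler: str = "constant"  # or "slanted_triangular"
    seed: int = 0
    clip_norm: float = 5.0
    constrain_decoding: bool = True
    max_len: int = 512

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not (32 <= self.hidden_dim <= 512):
            raise ValueError("hidden_dim must lie in [32, 512]")

    @classmethod
    def preset(cls, architecture: str, **overrides) -> "NERConfig":
        """Configuration carrying the published regime for *architecture*."""
        if architecture not in PRESETS:
            raise ValueError(f"no preset for {architecture!r}")
        kwargs = {"architecture": architecture, **PRESETS[architecture]}
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def has_crf(self) -> bool:
        return self.architecture.endswith("+crf")


class NERModel:
    """Token tagger: encoder stack + softmax or CRF head over 13 tags."""

    K = len(TAG_VOCAB)

    def __init__(self, vocab: dict[str, int], config: NERConfig) -> None:
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.embedding_dim
        h = config.hidden_dim
        self.embedding = _nn.Embedding(len(vocab), d, rng,
                                       frozen=config.freeze_embeddings)
        self.stack: list = []
        arch = config.architecture.replace("+crf", "")
        if arch == "recurrent":
            self.stack.append(("rnn", _nn.BiRecurrent(d, h, rng)))
            feat = 2 * h
        elif arch == "transformer":
            self.stack.append(("attn", _nn.SelfAttention(d, rng, config.max_len)))
            self.stack.append(("ffn", _nn.Dense(d, h, rng, activation="tanh")))
            feat = h
        elif arch == "transformer+recurrent":
            self.stack.append(("attn", _nn.SelfAttention(d, rng, config.max_len)))
            self.stack.append(("rnn", _nn.BiRecurrent(d, h, rng)))
            feat = 2 * h
        else:  # pragma: no cover - guarded by NERConfig
            raise ValueError(arch)
        self.out = _nn.Dense(feat, self.K, rng)
        self.crf_params: dict[str, np.ndarray] = {}
        if config.has_crf:
            self.crf_params = {
                "transitions": np.zeros((self.K, self.K)),
                "start": np.zeros(self.K),
                "end": np.zeros(self.K),
            }
        self.run_log: dict = {}

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        yield "emb", self.embedding
        for name, layer in self.stack:
            yield name, layer
        yield "out", self.out

    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        for prefix, layer in self._layers():
            for k in layer.trainable():
                params[f"{prefix}.{k}"] = layer.params[k]
        for k, v in self.crf_params.items():
            params[f"crf.{k}"] = v
        return params

    def _collect_grads(self, crf_grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        for prefix, layer in self._layers():
            for k in layer.trainable():
                grads[f"{prefix}.{k}"] = layer.grads[k]
        for k, v in crf_grads.items():
            grads[f"crf.{k}"] = v
        return grads

    def _zero(self) -> None:
        for _, layer in self._layers():
            layer.zero_grads()

    # -- forward ------------------------------------------------------------
    def token_ids(self, doc: Document) -> np.ndarray:
        """Vocabulary ids for a document's tokens (unknowns map to <unk>)."""
        return _nn.lookup_ids([t.text for t in doc.tokens], self.vocab)

    def emissions(self, ids: np.ndarray) -> np.ndarray:
        """(n, 13) emission score matrix for a token-id sequence."""
        if len(ids) == 0:
            raise ValueError("cannot encode an empty token sequence")
        x = self.embedding.forward(ids)
        for _, layer in self.stack:
            x = layer.forward(x)
        return self.out.forward(x)

    def _backprop_emissions(self, d_em: np.ndarray) -> None:
        d = self.out.backward(d_em)
        for _, layer in reversed(self.stack):
            d = layer.backward(d)
        self.embedding.backward(d)

    def loss_and_grads(self, ids: np.ndarray, tag_ids: np.ndarray):
        """Sequence loss (CRF NLL or mean token cross-entropy) and gradients."""
        self._zero()
        em = self.emissions(ids)
        if self.config.has_crf:
            nll, d_em, d_tr, d_start, d_end = crf_mod.crf_nll_gradients(
                em, self.crf_params["transitions"], self.crf_params["start"],
                self.crf_params["end"], tag_ids)
            crf_grads = {"transitions": d_tr, "start": d_start, "end": d_end}
            loss = nll
        else:
            loss, d_em = _nn.softmax_xent(em, tag_ids)
            crf_grads = {}
        self._backprop_emissions(d_em)
        return loss, self._collect_grads(crf_grads)

    # -- decoding -----------------------------------------------------------
    def _decode_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        tr = self.crf_params["transitions"]
        start = self.crf_params["start"]
        end = self.crf_params["end"]
        if self.config.constrain_decoding:
            tr, start = crf_mod.apply_constraints(tr, start)
        return tr, start, end

    def decode(self, ids: np.ndarray) -> tuple[list[str], list[float]]:
        """Predicted tags and per-token confidences for one sequence."""
        if len(ids) == 0:
            return [], []
        em = self.emissions(ids)
        if self.config.has_crf:
            tr, start, end = self._decode_matrices()
            tag_ids, _ = crf_mod.viterbi_decode(em, tr, start, end)
            post = crf_mod.forward_backward(em, tr, start, end)
            conf = post.unary[np.arange(len(ids)), tag_ids]
        else:
            probs = _nn.softmax(em, axis=1)
            tag_ids = probs.argmax(axis=1)
            conf = probs[np.arange(len(ids)), tag_ids]
        tags = [TAG_VOCAB[t] for t in tag_ids]
        return tags, [float(c) for c in conf]

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "ner_model.json").write_text(json.dumps({
            "vocab": self.vocab, "config": asdict(self.config),
            "run_log": self.run_log, "tag_vocab": list(TAG_VOCAB),
        }))
        arrays = dict(self.parameters())
        # frozen embeddings are not in parameters() but must persist
        arrays["emb.E"] = self.embedding.params["E"]
        np.savez(path / "ner_weights.npz", **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "NERModel":
        path = Path(path)
        meta = json.loads((path / "ner_model.json").read_text())
        if tuple(meta["tag_vocab"]) != TAG_VOCAB:
            raise ValueError("saved model uses an incompatible tag vocabulary")
        model = cls(meta["vocab"], NERConfig(**meta["config"]))
        with np.load(path / "ner_weights.npz") as data:
            for prefix, layer in model._layers():
                for k in layer.params:
                    key = f"{prefix}.{k}"
                    if key in data:
                        layer.params[k] = data[key]
            for k in model.crf_params:
                model.crf_params[k] = data[f"crf.{k}"]
        model.run_log = meta.get("run_log", {})
        return model


def load_word_vectors(path: str | Path, vocab: dict[str, int],
                      dim: int) -> np.ndarray:
    """Read whitespace-separated ``word v1 ... v_dim`` text vectors.

    Returns an embedding matrix aligned with *vocab*; words absent from the
    file keep small random vectors (seeded by the vocabulary size).
    """
    rng = np.random.default_rng(len(vocab))
    matrix = rng.normal(0.0, 0.1, size=(len(vocab), dim))
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split()
            if len(parts) != dim + 1:
                continue
            idx = vocab.get(parts[0].lower())
            if idx is not None:
                matrix[idx] = np.array([float(v) for v in parts[1:]])
    return matrix


def train_ner(
    train: list[Document], val: list[Document], config: NERConfig,
    *, embedding_file: str | Path | None = None,
) -> NERModel:
    """Train a tagger on PICO-truncated documents.

    One document is one training sequence.  CRF heads minimise the sequence
    NLL, softmax heads the mean per-token cross-entropy; the checkpoint with
    the best validation overall F1 (entity level, macro) is returned.
    Zero-token documents are skipped with a warning.  Deterministic under
    ``config.seed``.
    """
    usable = [d for d in train if d.tokens]
    if len(usable) < len(train):
        warnings.warn(f"skipped {len(train) - len(usable)} zero-token document(s)")
    if not usable:
        raise ValueError("no non-empty training documents")

    vocab = _nn.build_vocab(t.text for d in usable for t in d.tokens)
    model = NERModel(vocab, config)
    if embedding_file is not None:
        model.embedding.params["E"] = load_word_vectors(
            embedding_file, vocab, config.embedding_dim)

    examples = []
    for doc in usable:
        ids = model.token_ids(doc)
        tags = np.array([TAG_TO_INDEX[t]
                         for t in spans_to_bio(doc.tokens, doc.gold_spans)],
                        dtype=np.intp)
        examples.append((ids, tags))

    params = model.parameters()
    optimizer = _nn.AdamOptimizer(
        params, lr=config.lr,
        weight_decay=0.01 if config.optimizer == "adamw" else 0.0,
        decoupled_weight_decay=config.optimizer == "adamw")
    rng = np.random.default_rng(config.seed + 1)
    total_updates = config.epochs * len(examples)
    best: tuple[float, int, dict] | None = None
    history: list[dict] = []
    update = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(examples))
        epoch_loss = 0.0
        for i in order:
            ids, tags = examples[i]
            loss, grads = model.loss_and_grads(ids, tags)
            epoch_loss += loss
            _nn.clip_global_norm(grads, config.clip_norm)
            scale = (_nn.slanted_triangular(update, total_updates)
                     if config.scheduler == "slanted_triangular" else 1.0)
            optimizer.step(grads, lr_scale=scale)
            update += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / len(examples)}
        if val:
            scored = []
            for doc in val:
                tags, _ = predict_tags(model, doc)
                pred = bio_to_spans(doc.tokens, tags, repair=True, text=doc.text)
                scored.append(metrics.entity_prf(pred, doc.gold_spans))
            f1 = metrics.aggregate(scored).overall.f1
            record["val_f1"] = f1
            if best is None or f1 > best[0]:
                snapshot = {k: v.copy() for k, v in model.parameters().items()}
                snapshot["emb.E"] = model.embedding.params["E"].copy()
                best = (f1, epoch, snapshot)
        history.append(record)

    if val and best is not None:
        for prefix, layer in model._layers():
            for k in layer.params:
                key = f"{prefix}.{k}"
                if key in best[2]:
                    layer.params[k] = best[2][key]
        for k in model.crf_params:
            model.crf_params[k] = best[2][f"crf.{k}"]
        best_epoch, best_f1 = best[1], best[0]
    else:
        best_epoch, best_f1 = config.epochs - 1, float("nan")
    model.run_log = {
        "architecture": config.architecture, "lr": config.lr,
        "epochs": config.epochs, "hidden_dim": config.hidden_dim,
        "embedding_dim": config.embedding_dim,
        "freeze_embeddings": config.freeze_embeddings,
        "optimizer": config.optimizer, "scheduler": config.scheduler,
        "seed": config.seed, "best_epoch": best_epoch, "best_val_f1": best_f1,
        "history": history,
    }
    return model


def predict_tags(model: NERModel, doc: Document) -> tuple[list[str], list[float]]:
    """Tags and per-token confidences for every token of *doc*.

    Empty documents yield empty outputs.  Confidences are the posterior
    probability of the emitted tag at each position.
    """
    if not doc.tokens:
        return [], []
    return model.decode(model.token_ids(doc))


def predict_spans(model: NERModel, doc: Document):
    """Decode *doc* and return (spans, tags, confidences)."""
    tags, conf = predict_tags(model, doc)
    spans = bio_to_spans(doc.tokens, tags, repair=True, text=doc.text)
    return spans, tags, conf
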