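"""Minimal NumPy neural-network toolkit used by both pipeline stages.

Layers implement explicit forward/backward passes (no autodiff); every layer
is gradient-checked against central finite differences in the test suite.
Parameters live in per-layer ``params`` dicts; gradients accumulate in a
parallel ``grads`` dict that the optimizer consumes.

Included: token embedding lookup, bidirectional tanh recurrent layer,
single-head scaled-dot-product self-attention with learned positions, dense
layers, softmax cross-entropy, Adam/AdamW with global-norm gradient clipping,
and the slanted-triangular learning-rate schedule (short linear warm-up,
long linear decay).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

UNK = "<unk>"


def build_vocab(token_iter: Iterable[str], lowercase: bool = True) -> dict[str, int]:
    """Index vocabulary from training tokens; index 0 is the unknown word."""
    vocab = {UNK: 0}
    for tok in token_iter:
        key = tok.lower() if lowercase else tok
        if key not in vocab:
            vocab[key] = len(vocab)
    return vocab


def lookup_ids(tokens: Iterable[str], vocab: dict[str, int],
               lowercase: bool = True) -> np.ndarray:
    return np.array(
        [vocab.get(t.lower() if lowercase else t, 0) for t in tokens],
        dtype=np.intp,
    )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Layer:
    """Base: ``params``/``grads`` dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        for name, p in self.params.items():
            self.grads[name] = np.zeros_like(p)

    def named_params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.{k}": v for k, v in self.params.items()}


class Embedding(Layer):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator,
                 frozen: bool = False) -> None:
        super().__init__()
        self.frozen = frozen
        self.params["E"] = rng.normal(0.0, 0.1, size=(vocab_size, dim))
        self.zero_grads()
        self._ids: np.ndarray | None = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.params["E"][ids]

    def backward(self, d_out: np.ndarray) -> None:
        if not self.frozen:
            np.add.at(self.grads["E"], self._ids, d_out)

    def trainable(self) -> list[str]:
        return [] if self.frozen else ["E"]


class Dense(Layer):
    """Affine map with optional tanh, applied row-wise to (n, d_in)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str = "linear") -> None:
        super().__init__()
        if activation not in ("linear", "tanh"):
            raise ValueError(activation)
        self.activation = activation
        self.params["W"] = _glorot(rng, d_in, d_out)
        self.params["b"] = np.zeros(d_out)
        self.zero_grads()
        self._x: np.ndarray | None = None
        self._h: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        h = x @ self.params["W"] + self.params["b"]
        if self.activation == "tanh":
            h = np.tanh(h)
        self._h = h
        return h

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            d_out = d_out * (1.0 - self._h ** 2)
        self.grads["W"] += self._x.T @ d_out
        self.grads["b"] += d_out.sum(axis=0)
        return d_out @ self.params["W"].T

    def trainable(self) -> list[str]:
        return ["W", "b"]


class BiRecurrent(Layer):
    """Bidirectional tanh recurrent layer.

    h_t = tanh(W_x x_t + W_h h_{t-1} + b), run left-to-right and
    right-to-left with separate parameters; output is the concatenation
    (n, 2*hidden).  Backward is full backpropagation through time.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        for tag in ("f", "b"):
            self.params[f"Wx_{tag}"] = _glorot(rng, d_in, hidden)
            self.params[f"Wh_{tag}"] = _glorot(rng, hidden, hidden)
            self.params[f"b_{tag}"] = np.zeros(hidden)
        self.zero_grads()
        self._cache: dict | None = None

    def _run(self, x: np.ndarray, tag: str, reverse: bool) -> np.ndarray:
        n = x.shape[0]
        wx, wh, b = (self.params[f"Wx_{tag}"], self.params[f"Wh_{tag}"],
                     self.params[f"b_{tag}"])
        order = range(n - 1, -1, -1) if reverse else range(n)
        h = np.zeros((n, self.hidden))
        prev = np.zeros(self.hidden)
        for t in order:
            prev = np.tanh(x[t] @ wx + prev @ wh + b)
            h[t] = prev
        return h

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self._run(x, "f", reverse=False)
        hb = self._run(x, "b", reverse=True)
        self._cache = {"x": x, "hf": hf, "hb": hb}
        return np.concatenate([hf, hb], axis=1)

    def _bptt(self, x: np.ndarray, h: np.ndarray, d_h: np.ndarray, tag: str,
              reverse: bool) -> np.ndarray:
        n = x.shape[0]
        wx, wh = self.params[f"Wx_{tag}"], self.params[f"Wh_{tag}"]
        d_x = np.zeros_like(x)
        carry = np.zeros(self.hidden)
        order = range(n) if reverse else range(n - 1, -1, -1)
        for t in order:
            dh = d_h[t] + carry
            da = dh * (1.0 - h[t] ** 2)
            if reverse:
                prev = h[t + 1] if t + 1 < n else np.zeros(self.hidden)
            else:
                prev = h[t - 1] if t > 0 else np.zeros(self.hidden)
            self.grads[f"Wx_{tag}"] += np.outer(x[t], da)
            self.grads[f"Wh_{tag}"] += np.outer(prev, da)
            self.grads[f"b_{tag}"] += da
            d_x[t] += wx @ da
            carry = wh @ da
        return d_x

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        c = self._cache
        d_hf = d_out[:, :self.hidden]
        d_hb = d_out[:, self.hidden:]
        d_x = self._bptt(c["x"], c["hf"], d_hf, "f", reverse=False)
        d_x += self._bptt(c["x"], c["hb"], d_hb, "b", reverse=True)
        return d_x

    def trainable(self) -> list[str]:
        return list(self.params)


class SelfAttention(Layer):
    """Single-head scaled-dot-product self-attention with residual output.

    out = x + softmax(x Wq (x Wk)^T / sqrt(d)) (x Wv) Wo.
    Learned positional embeddings are added to the input before attention so
    the layer is order-aware (attention alone is permutation-equivariant).
    """

    def __init__(self, dim: int, rng: np.random.Generator, max_len: int = 512) -> None:
        super().__init__()
        self.dim = dim
        self.max_len = max_len
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self.params[name] = _glorot(rng, dim, dim)
        self.params["P"] = rng.normal(0.0, 0.1, size=(max_len, dim))
        self.zero_grads()
        self._cache: dict | None = None

    def forward(self, x_in: np.ndarray) -> np.ndarray:
        n = x_in.shape[0]
        if n > self.max_len:
            raise ValueError(f"sequence length {n} exceeds max_len {self.max_len}")
        x = x_in + self.params["P"][:n]
        q = x @ self.params["Wq"]
        k = x @ self.params["Wk"]
        v = x @ self.params["Wv"]
        scores = q @ k.T / math.sqrt(self.dim)
        scores -= scores.max(axis=1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=1, keepdims=True)
        context = attn @ v
        out = x + context @ self.params["Wo"]
        self._cache = {"x": x, "q": q, "k": k, "v": v, "attn": attn,
                       "context": context, "n": n}
        return out

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        c = self._cache
        x, q, k, v, attn = c["x"], c["q"], c["k"], c["v"], c["attn"]
        d_x = d_out.copy()
        d_context = d_out @ self.params["Wo"].T
        self.grads["Wo"] += c["context"].T @ d_out
        d_attn = d_context @ v.T
        d_v = attn.T @ d_context
        # softmax rows: dS_ij = A_ij * (dA_ij - sum_k dA_ik A_ik)
        d_scores = attn * (d_attn - (d_attn * attn).sum(axis=1, keepdims=True))
        d_scores /= math.sqrt(self.dim)
        d_q = d_scores @ k
        d_k = d_scores.T @ q
        self.grads["Wq"] += x.T @ d_q
        self.grads["Wk"] += x.T @ d_k
        self.grads["Wv"] += x.T @ d_v
        d_x += d_q @ self.params["Wq"].T
        d_x += d_k @ self.params["Wk"].T
        d_x += d_v @ self.params["Wv"].T
        self.grads["P"][:c["n"]] += d_x
        return d_x

    def trainable(self) -> list[str]:
        return list(self.params)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows and its gradient w.r.t. logits."""
    n = logits.shape[0]
    probs = softmax(logits, axis=1)
    nll = -np.log(np.clip(probs[np.arange(n), targets], 1e-300, None)).mean()
    d = probs.copy()
    d[np.arange(n), targets] -= 1.0
    return float(nll), d / n


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Rescale all gradients in place so the global L2 norm is <= max_norm."""
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


def slanted_triangular(step: int, total_steps: int, cut_frac: float = 0.1,
                       ratio: float = 32.0) -> float:
    """Multiplier in (0, 1]: linear warm-up for ``cut_frac`` of training,
    then linear decay to 1/ratio of the peak."""
    if total_steps <= 0:
        return 1.0
    cut = max(1.0, math.floor(total_steps * cut_frac))
    t = min(step, total_steps)
    if t < cut:
        p = t / cut
    else:
        p = 1.0 - (t - cut) / max(1.0, total_steps - cut)
    return (1.0 + p * (ratio - 1.0)) / ratio


class AdamOptimizer:
    """Adam / AdamW over a flat dict of named parameter arrays.

    ``decoupled_weight_decay`` selects AdamW (decay applied directly to the
    weights, not through the gradient).
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 decoupled_weight_decay: bool = True) -> None:
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled_weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr_scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.betas
        lr = self.lr * lr_scale
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for name, p in self.params.items():
            g = grads[name]
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / bias1
            v_hat = self.v[name] / bias2
            if self.weight_decay and self.decoupled:
                p -= lr * self.weight_decay * p
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
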