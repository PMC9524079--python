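"""Linear-chain conditional random field over BIO tag sequences.

A tag sequence y for a length-n token sequence is scored as

    score(y) = start[y_1] + sum_t emissions[t, y_t]
             + sum_t transitions[y_{t-1}, y_t] + end[y_n]

and the CRF defines p(y) = exp(score(y)) / Z with Z the sum over all K^n
sequences, computed by the forward recursion in log space.  Decoding is
Viterbi; per-token posteriors come from forward-backward.

Hard BIO constraints are expressed by setting the scores of illegal
transitions (``I-T`` after anything other than ``B-T``/``I-T`` of the same
type, or at sequence start) to -inf, which guarantees structurally valid
output from constrained decoding.

All functions are pure NumPy and also return the gradients needed to train
emission/transition parameters by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .corpus import TAG_VOCAB, OUTSIDE

NEG_INF = -np.inf


def _check_shapes(emissions: np.ndarray, transitions: np.ndarray,
                  start: np.ndarray, end: np.ndarray) -> tuple[int, int]:
    emissions = np.asarray(emissions)
    if emissions.ndim != 2 or emissions.shape[0] == 0:
        raise ValueError("emissions must be a non-empty (n, K) matrix")
    n, k = emissions.shape
    if transitions.shape != (k, k) or start.shape != (k,) or end.shape != (k,):
        raise ValueError("transition/start/end shapes inconsistent with emissions")
    return n, k


def path_score(emissions: np.ndarray, transitions: np.ndarray,
               start: np.ndarray, end: np.ndarray, tags: np.ndarray) -> float:
    """Unnormalized log score of one tag sequence."""
    n, _ = _check_shapes(emissions, transitions, start, end)
    tags = np.asarray(tags)
    if tags.shape != (n,):
        raise ValueError(f"expected {n} tags, got {tags.shape}")
    score = start[tags[0]] + emissions[np.arange(n), tags].sum() + end[tags[-1]]
    score += transitions[tags[:-1], tags[1:]].sum()
    return float(score)


def crf_partition(emissions: np.ndarray, transitions: np.ndarray,
                  start: np.ndarray, end: np.ndarray) -> float:
    """log Z: log-sum-exp of path scores over all tag sequences."""
    n, _ = _check_shapes(emissions, transitions, start, end)
    alpha = start + emissions[0]
    for t in range(1, n):
        alpha = logsumexp(alpha[:, None] + transitions, axis=0) + emissions[t]
    return float(logsumexp(alpha + end))


def crf_nll(emissions: np.ndarray, transitions: np.ndarray,
            start: np.ndarray, end: np.ndarray, tags: np.ndarray) -> float:
    """Negative log likelihood of *tags*; non-negative up to rounding."""
    return crf_partition(emissions, transitions, start, end) - path_score(
        emissions, transitions, start, end, tags)


def viterbi_decode(emissions: np.ndarray, transitions: np.ndarray,
                   start: np.ndarray, end: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-scoring tag sequence and its score.

    Ties are broken toward the lowest tag index at every backtracking step
    (``np.argmax`` keeps the first maximum), so an all-zero score instance
    decodes to all-``O`` under the canonical vocabulary where O is index 0.
    """
    n, k = _check_shapes(emissions, transitions, start, end)
    delta = start + emissions[0]
    backptr = np.zeros((n, k), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + transitions  # (from, to)
        backptr[t] = np.argmax(cand, axis=0)
        delta = cand[backptr[t], np.arange(k)] + emissions[t]
    final = delta + end
    best_last = int(np.argmax(final))
    best_score = float(final[best_last])
    if not np.isfinite(best_score):
        raise ValueError("no tag sequence with finite score")
    tags = np.empty(n, dtype=np.intp)
    tags[-1] = best_last
    for t in range(n - 1, 0, -1):
        tags[t - 1] = backptr[t, tags[t]]
    return tags, best_score


@dataclass
class Posteriors:
    """Forward-backward output: log Z and marginal distributions."""

    log_partition: float
    unary: np.ndarray      # (n, K); unary[t, y] = p(y_t = y)
    pairwise: np.ndarray   # (n-1, K, K); p(y_t = i, y_{t+1} = j)


def forward_backward(emissions: np.ndarray, transitions: np.ndarray,
                     start: np.ndarray, end: np.ndarray) -> Posteriors:
    """Exact token and transition marginals under the CRF."""
    n, k = _check_shapes(emissions, transitions, start, end)
    log_alpha = np.empty((n, k))
    log_alpha[0] = start + emissions[0]
    for t in range(1, n):
        log_alpha[t] = logsumexp(log_alpha[t - 1][:, None] + transitions,
                                 axis=0) + emissions[t]
    log_beta = np.empty((n, k))
    log_beta[-1] = end
    for t in range(n - 2, -1, -1):
        log_beta[t] = logsumexp(transitions + (emissions[t + 1] + log_beta[t + 1])[None, :],
                                axis=1)
    log_z = float(logsumexp(log_alpha[-1] + end))
    with np.errstate(invalid="ignore"):
        unary = np.exp(log_alpha + log_beta - log_z)
    unary = np.nan_to_num(unary, nan=0.0)
    pairwise = np.zeros((max(n - 1, 0), k, k))
    for t in range(n - 1):
        log_pair = (log_alpha[t][:, None] + transitions
                    + (emissions[t + 1] + log_beta[t + 1])[None, :] - log_z)
        with np.errstate(invalid="ignore"):
            pairwise[t] = np.nan_to_num(np.exp(log_pair), nan=0.0)
    return Posteriors(log_partition=log_z, unary=unary, pairwise=pairwise)


def crf_nll_gradients(
    emissions: np.ndarray, transitions: np.ndarray,
    start: np.ndarray, end: np.ndarray, tags: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NLL and its gradients w.r.t. emissions, transitions, start, end.

    The gradient of -log p(y) is (model expectation - empirical count) for
    every score parameter, read off the forward-backward marginals.
    """
    n, k = _check_shapes(emissions, transitions, start, end)
    tags = np.asarray(tags)
    post = forward_backward(emissions, transitions, start, end)
    nll = post.log_partition - path_score(emissions, transitions, start, end, tags)
    d_em = post.unary.copy()
    d_em[np.arange(n), tags] -= 1.0
    d_tr = post.pairwise.sum(axis=0)
    np.add.at(d_tr, (tags[:-1], tags[1:]), -1.0)
    d_start = post.unary[0].copy()
    d_start[tags[0]] -= 1.0
    d_end = post.unary[-1].copy()
    d_end[tags[-1]] -= 1.0
    return float(nll), d_em, d_tr, d_start, d_end


def bio_constraint_masks(
    vocab: tuple[str, ...] = TAG_VOCAB,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of legal BIO transitions.

    Returns ``(allowed, allowed_start)`` where ``allowed[i, j]`` permits tag j
    to follow tag i, and ``allowed_start[j]`` permits tag j at position 1.
    ``I-T`` is legal only after ``B-T`` or ``I-T`` of the same type and never
    sequence-initial; everything else is legal.
    """
    k = len(vocab)
    allowed = np.ones((k, k), dtype=bool)
    allowed_start = np.ones(k, dtype=bool)
    for j, tag in enumerate(vocab):
        if not tag.startswith("I-"):
            continue
        allowed_start[j] = False
        same = {f"B-{tag[2:]}", tag}
        for i, prev in enumerate(vocab):
            allowed[i, j] = prev in same
    return allowed, allowed_start


def apply_constraints(transitions: np.ndarray, start: np.ndarray,
                      vocab: tuple[str, ...] = TAG_VOCAB) -> tuple[np.ndarray, np.ndarray]:
    """Copies of transition/start scores with illegal BIO moves at -inf."""
    allowed, allowed_start = bio_constraint_masks(vocab)
    return (np.where(allowed, transitions, NEG_INF),
            np.where(allowed_start, start, NEG_INF))
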