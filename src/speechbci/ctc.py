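"""Connectionist temporal classification: loss, gradient, greedy decoding.

CTC scores a label sequence against a frame-wise posteriorgram by summing
the probabilities of every frame-level alignment that collapses to it
(consecutive repeats merged, blanks deleted).  The forward-backward
recursion runs over the blank-augmented label lattice in log space.  The
gradient is returned with respect to the pre-softmax logits, which is what
the recurrent decoder trains against.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

NEG_INF = -np.inf


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def _extend(target: Sequence[int], blank: int) -> np.ndarray:
    ext = np.full(2 * len(target) + 1, blank, dtype=int)
    ext[1::2] = target
    return ext


def ctc_forward_logprob(logp: np.ndarray, target: Sequence[int], blank: int) -> float:
    """log P(target | posteriorgram) by the forward recursion.

    ``logp``: (T, C) log probabilities.  Returns -inf when the target cannot
    fit in T frames (after mandatory blanks between repeated labels).
    """
    T = logp.shape[0]
    target = list(target)
    if len(target) == 0:
        return float(logp[:, blank].sum())
    ext = _extend(target, blank)
    S = len(ext)
    alpha = np.full(S, NEG_INF)
    alpha[0] = logp[0, ext[0]]
    if S > 1:
        alpha[1] = logp[0, ext[1]]
    for t in range(1, T):
        prev = alpha
        alpha = np.full(S, NEG_INF)
        for s in range(S):
            a = prev[s]
            if s >= 1:
                a = np.logaddexp(a, prev[s - 1])
            if s >= 2 and ext[s] != blank and ext[s] != ext[s - 2]:
                a = np.logaddexp(a, prev[s - 2])
            alpha[s] = a + logp[t, ext[s]]
    out = alpha[S - 1]
    if S > 1:
        out = np.logaddexp(out, alpha[S - 2])
    return float(out)


def ctc_loss_and_grad(
    logits: np.ndarray, target: Sequence[int], blank: int
) -> Tuple[float, np.ndarray]:
    """CTC negative log-likelihood and its gradient w.r.t. the logits.

    Returns ``(nll, grad)`` with ``grad`` shaped like ``logits``.  If the
    target is too long for the number of frames the loss is +inf and the
    gradient zero (callers skip such trials with a warning).
    """
    logp = log_softmax(logits)
    T, C = logp.shape
    target = list(target)
    ext = _extend(target, blank)
    S = len(ext)
    if T < len(target) + sum(1 for i in range(1, len(target))
                             if target[i] == target[i - 1]):
        return np.inf, np.zeros_like(logits)

    alpha = np.full((T, S), NEG_INF)
    alpha[0, 0] = logp[0, ext[0]]
    if S > 1:
        alpha[0, 1] = logp[0, ext[1]]
    for t in range(1, T):
        prev = alpha[t - 1]
        a = prev.copy()
        a[1:] = np.logaddexp(a[1:], prev[:-1])
        skip = np.zeros(S, dtype=bool)
        skip[2:] = (ext[2:] != blank) & (ext[2:] != ext[:-2])
        a[skip] = np.logaddexp(a[skip], prev[np.flatnonzero(skip) - 2])
        alpha[t] = a + logp[t, ext]

    beta = np.full((T, S), NEG_INF)
    beta[T - 1, S - 1] = logp[T - 1, ext[S - 1]]
    if S > 1:
        beta[T - 1, S - 2] = logp[T - 1, ext[S - 2]]
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1]
        b = nxt.copy()
        b[:-1] = np.logaddexp(b[:-1], nxt[1:])
        skip = np.zeros(S, dtype=bool)
        skip[:-2] = (ext[:-2] != blank) & (ext[:-2] != ext[2:])
        b[skip] = np.logaddexp(b[skip], nxt[np.flatnonzero(skip) + 2])
        beta[t] = b + logp[t, ext]

    ll = np.logaddexp(alpha[T - 1, S - 1],
                      alpha[T - 1, S - 2] if S > 1 else NEG_INF)
    if not np.isfinite(ll):
        return np.inf, np.zeros_like(logits)

    # gamma[t, k]: posterior that frame t emits token k, given the target
    with np.errstate(invalid="ignore"):
        occ = alpha + beta - logp[:, ext]  # alpha*beta double-counts logp
    gamma = np.zeros((T, C))
    for s in range(S):
        gamma[:, ext[s]] += np.exp(occ[:, s] - ll)
    grad = np.exp(logp) - gamma
    return float(-ll), grad


def greedy_decode(posteriorgram: np.ndarray, blank: int) -> List[int]:
    """Best-path decoding: per-step argmax, collapse repeats, drop blanks.

    SIL is an ordinary token here and survives as a word-boundary marker.
    """
    path = np.argmax(posteriorgram, axis=1)
    out: List[int] = []
    prev = -1
    for p in path:
        if p != prev and p != blank:
            out.append(int(p))
        prev = p
    return out


def collapse(path: Sequence[int], blank: int) -> List[int]:
    """CTC collapse of an explicit frame-label path (test utility)."""
    out: List[int] = []
    prev = -1
    for p in path:
        if p != prev and p != blank:
            out.append(int(p))
        prev = p
    return out
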