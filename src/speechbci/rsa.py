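"""Saliency vectors and representational similarity analysis.

A phoneme's saliency vector is the unit-norm input-space direction that
maximizes the decoder's output probability for that phoneme — found by
projected gradient ascent on a short constant-input window, best of several
seeded restarts.  The pairwise cosine structure of saliency vectors is then
compared with the articulatory feature structure: Pearson correlation over
the strictly-upper-triangle entries, significance by joint row/column
permutation of one matrix, low-dimensional geometry by cross-validated
orthogonal Procrustes in the top principal components, and a direct
least-squares "vowel plane" fit of the 2-D height/backness coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.stats import pearsonr

from .ctc import log_softmax
from .rnn import GRUDecoder


@dataclass
class SaliencyResult:
    vector: np.ndarray
    objective: float          # best achieved mean center-step probability
    converged: bool
    n_restarts: int
    n_iters: int


def extract_saliency(
    decoder: GRUDecoder,
    token: int,
    day: int = 0,
    n_restarts: int = 3,
    n_steps: int = 6,
    n_iters: int = 60,
    lr: float = 0.5,
    tol: float = 1e-3,
    seed: int = 0,
) -> SaliencyResult:
    """Unit-norm input maximizing the token's probability at the center step.

    The input is one vector repeated over ``n_steps`` decoder steps;
    gradient ascent on the sphere (gradient projected to the tangent space,
    renormalized each iterate).  The blank token is rejected: it has no
    articulatory meaning.
    """
    C = decoder.config.n_tokens
    if token == C - 1:
        raise ValueError("saliency of the CTC blank token is not defined")
    if not 0 <= token < C:
        raise ValueError(f"token {token} out of range")
    D = decoder.config.input_dim
    center = n_steps // 2
    rng = np.random.default_rng(seed)
    best: Optional[SaliencyResult] = None
    for _ in range(n_restarts):
        v = rng.normal(size=D)
        v /= np.linalg.norm(v)
        converged = False
        for it in range(n_iters):
            x = np.tile(v, (n_steps, 1))
            logits, caches = decoder.forward(x[None], day, cache=True)
            logp = log_softmax(logits[0])
            probs = np.exp(logp)
            # d(mean center prob)/d(logits): softmax jacobian row at center
            dlogits = np.zeros_like(logits)
            dlogits[0, center] = probs[center, token] * (
                (np.arange(C) == token) - probs[center])
            _, dx = decoder.backward(caches, dlogits)
            g = dx[0].sum(axis=0)
            g -= (g @ v) * v          # tangent projection
            gnorm = np.linalg.norm(g)
            if gnorm < tol:
                converged = True
                break
            v = v + lr * g
            v /= np.linalg.norm(v)
        obj = float(np.exp(log_softmax(
            decoder.forward(np.tile(v, (n_steps, 1))[None], day)[0]
        ))[center, token])
        cand = SaliencyResult(v.copy(), obj, converged, n_restarts, n_iters)
        if best is None or cand.objective > best.objective:
            best = cand
    return best


def gradient_at_baseline(
    decoder: GRUDecoder, token: int, day: int = 0, n_steps: int = 6
) -> np.ndarray:
    """Alternative estimator: normalized input gradient at zero input."""
    C = decoder.config.n_tokens
    center = n_steps // 2
    x = np.zeros((n_steps, decoder.config.input_dim))
    logits, caches = decoder.forward(x[None], day, cache=True)
    probs = np.exp(log_softmax(logits[0]))
    dlogits = np.zeros_like(logits)
    dlogits[0, center] = probs[center, token] * (
        (np.arange(C) == token) - probs[center])
    _, dx = decoder.backward(caches, dlogits)
    g = dx[0].sum(axis=0)
    return g / np.linalg.norm(g)


@dataclass
class SimilarityMatrix:
    labels: List[str]
    matrix: np.ndarray
    ordering: str = "custom"

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix/label shape mismatch")

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.matrix[iu]

    def reorder(self, labels: Sequence[str], ordering: str = "custom"):
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(list(labels),
                                self.matrix[np.ix_(idx, idx)], ordering)


def similarity_matrix(
    vectors: Dict[str, np.ndarray] | np.ndarray,
    ordering: Sequence[str] | None = None,
    tag: str = "custom",
) -> SimilarityMatrix:
    """Pairwise cosine similarities, rows ordered by ``ordering``."""
    if isinstance(vectors, dict):
        labels = list(ordering) if ordering is not None else sorted(vectors)
        X = np.stack([vectors[l] for l in labels])
    else:
        X = np.asarray(vectors)
        labels = list(ordering) if ordering is not None \
            else [str(i) for i in range(X.shape[0])]
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero vector has no cosine similarity")
    Xn = X / norms
    M = np.clip(Xn @ Xn.T, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(labels, (M + M.T) / 2, tag)


def rsa_correlation(neural: SimilarityMatrix, artic: SimilarityMatrix) -> float:
    """Pearson r over strictly-upper-triangle entries (diagonal excluded)."""
    if neural.labels != artic.labels:
        artic = artic.reorder(neural.labels)
    return float(pearsonr(neural.upper(), artic.upper())[0])


def permutation_null(
    neural: SimilarityMatrix,
    artic: SimilarityMatrix,
    n: int = 10000,
    seed: int = 0,
) -> Tuple[np.ndarray, float, float]:
    """Label-reshuffling null for the RSA correlation.

    Rows and columns of the articulatory matrix are permuted jointly per
    reshuffle.  Returns (null distribution, observed r, p-value) with
    ``p = (1 + #{null >= observed}) / (n + 1)``.
    """
    if neural.labels != artic.labels:
        artic = artic.reorder(neural.labels)
    observed = rsa_correlation(neural, artic)
    rng = np.random.default_rng(seed)
    k = len(neural.labels)
    iu = np.triu_indices(k, 1)
    nu = neural.matrix[iu]
    nulls = np.empty(n)
    A = artic.matrix
    for i in range(n):
        perm = rng.permutation(k)
        av = A[np.ix_(perm, perm)][iu]
        nulls[i] = pearsonr(nu, av)[0]
    p = (1 + int(np.sum(nulls >= observed))) / (n + 1)
    return nulls, observed, p


def cv_procrustes(
    neural_vectors: np.ndarray,
    artic_coords: np.ndarray,
    n_pcs: int = 8,
) -> Tuple[np.ndarray, float]:
    """Cross-validated Procrustes alignment of neural geometry to 2-D
    articulatory coordinates.

    Neural vectors (n x D) are centered and projected onto their top
    ``n_pcs`` principal components; the articulatory coordinates (n x 2)
    are zero-padded into that space.  For each held-out phoneme, an
    orthogonal rotation plus global scale is fitted on the rest and used to
    place the held-out point.  Returns the aligned 2-D coordinates and the
    cross-validated disparity (mean squared residual against the
    articulatory coordinates).
    """
    X = np.asarray(neural_vectors, dtype=float)
    Y2 = np.asarray(artic_coords, dtype=float)
    n = X.shape[0]
    if n_pcs > min(X.shape[1], n - 1):
        raise ValueError("n_pcs exceeds available dimensionality")
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ Vt[:n_pcs].T                     # (n, n_pcs)
    Ypad = np.zeros((n, n_pcs))
    Yc_mean = Y2.mean(axis=0)
    Ypad[:, :2] = Y2 - Yc_mean

    aligned = np.empty((n, 2))
    for i in range(n):
        mask = np.arange(n) != i
        A, B = scores[mask], Ypad[mask]
        R, s = orthogonal_procrustes(A, B)
        scale = s / (A * A).sum()
        aligned[i] = (scale * scores[i] @ R)[:2] + Yc_mean
    disparity = float(((aligned - Y2) ** 2).mean())
    return aligned, disparity


def vowel_plane(
    neural_vectors: np.ndarray,
    coords_2d: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane in neural space spanned by 2-D vowel coordinates.

    Fits ``neural ≈ mean + coords @ B`` (B: 2 x D).  Returns (B, projected
    2-D coordinates of each neural vector on the fitted plane, R² of the
    fit).
    """
    X = np.asarray(neural_vectors, dtype=float)
    C = np.asarray(coords_2d, dtype=float)
    Xc = X - X.mean(axis=0)
    Cc = C - C.mean(axis=0)
    B, *_ = np.linalg.lstsq(Cc, Xc, rcond=None)
    resid = Xc - Cc @ B
    ss_tot = float((Xc ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    projected = Xc @ np.linalg.pinv(B) + C.mean(axis=0)
    return B, projected, r2


def saliency_set_to_csv(vectors: Dict[str, np.ndarray], path) -> None:
    import pandas as pd
    df = pd.DataFrame({ph: v for ph, v in sorted(vectors.items())}).T
    df.index.name = "phoneme"
    df.to_csv(path)
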