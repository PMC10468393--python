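"""Feature preprocessing: smoothing, z-scoring, rolling adaptation, stacking.

A trial's feature block is the bins x (2 * electrodes) matrix of
threshold-crossing counts concatenated with spike-band power at the native
20 ms resolution.  Two smoothing paths exist: an acausal Gaussian kernel
(80 ms s.d. default) for display/analysis PSTHs, and a short causal boxcar
for the decoder path, which must not look ahead.  Rolling adaptation keeps
causal exponentially weighted running statistics per column to absorb slow
within-day drift; ordinary block z-scoring uses frozen training-set
statistics.  Temporal stacking concatenates k=4 consecutive 20 ms bins into
the decoder's 80 ms step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

SD_FLOOR = 1e-3  # silent-electrode guard in every normalization


def make_block(trial) -> np.ndarray:
    """bins x (2*electrodes): [tx | sbp]."""
    return np.concatenate([trial.tx, trial.sbp], axis=1)


def gaussian_smooth(block: np.ndarray, sd_ms: float, bin_ms: float = 20.0) -> np.ndarray:
    """Acausal Gaussian smoothing per column (truncated at ±4 s.d.)."""
    if sd_ms <= 0:
        raise ValueError("sd_ms must be positive")
    return gaussian_filter1d(
        np.asarray(block, dtype=float), sigma=sd_ms / bin_ms,
        axis=0, mode="reflect", truncate=4.0,
    )


def causal_boxcar(block: np.ndarray, k: int = 2) -> np.ndarray:
    """Average of the current and previous k-1 bins (no lookahead)."""
    if k <= 1:
        return np.asarray(block, dtype=float)
    x = np.asarray(block, dtype=float)
    c = np.cumsum(np.concatenate([np.zeros((1, x.shape[1])), x], axis=0), axis=0)
    out = np.empty_like(x)
    for t in range(x.shape[0]):
        lo = max(0, t - k + 1)
        out[t] = (c[t + 1] - c[lo]) / (t + 1 - lo)
    return out


def column_stats(blocks: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled per-column mean and s.d. (floored) across trials."""
    x = np.concatenate([np.asarray(b, dtype=float) for b in blocks], axis=0)
    return x.mean(axis=0), np.maximum(x.std(axis=0), SD_FLOOR)


def block_zscore(
    blocks: Sequence[np.ndarray],
    stats_source: Sequence[np.ndarray] | Tuple[np.ndarray, np.ndarray] | None = None,
) -> List[np.ndarray]:
    """Z-score each block with statistics pooled from ``stats_source``.

    ``stats_source`` may be a list of blocks (e.g. the training day), a
    precomputed ``(mean, sd)`` pair, or None (use ``blocks`` themselves).
    """
    if stats_source is None:
        mean, sd = column_stats(blocks)
    elif isinstance(stats_source, tuple) and len(stats_source) == 2 \
            and isinstance(stats_source[0], np.ndarray) and stats_source[0].ndim == 1:
        mean, sd = stats_source[0], np.maximum(stats_source[1], SD_FLOOR)
    else:
        mean, sd = column_stats(stats_source)
    return [(np.asarray(b, dtype=float) - mean) / sd for b in blocks]


@dataclass
class RollingStats:
    """Causal exponentially weighted per-column mean/variance.

    ``decay`` is the per-bin retention factor, derived from a half-life in
    seconds.  The state normalizing bin t was computed from bins strictly
    before t, so adaptation never looks ahead; state persists across trial
    boundaries within a session.
    """

    mean: np.ndarray
    var: np.ndarray
    decay: float

    @classmethod
    def from_half_life(cls, half_life_s: float, init_mean: np.ndarray,
                       init_sd: np.ndarray, bin_s: float = 0.02) -> "RollingStats":
        if half_life_s <= 0:
            raise ValueError("half-life must be positive")
        decay = 0.5 ** (bin_s / half_life_s)
        return cls(init_mean.astype(float).copy(),
                   np.maximum(init_sd.astype(float), SD_FLOOR) ** 2, decay)

    def normalize_block(self, block: np.ndarray) -> np.ndarray:
        x = np.asarray(block, dtype=float)
        out = np.empty_like(x)
        m, v, lam = self.mean, self.var, self.decay
        for t in range(x.shape[0]):
            out[t] = (x[t] - m) / np.maximum(np.sqrt(v), SD_FLOOR)
            delta = x[t] - m
            m = lam * m + (1 - lam) * x[t]
            v = lam * (v + (1 - lam) * delta * delta)
        self.mean, self.var = m, v
        return out

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(),
                           "var": self.var.tolist(), "decay": self.decay})

    @classmethod
    def from_json(cls, s: str) -> "RollingStats":
        d = json.loads(s)
        return cls(np.array(d["mean"]), np.array(d["var"]), d["decay"])


def rolling_adapt(
    blocks: Iterable[np.ndarray],
    half_life_s: float,
    init_mean: np.ndarray,
    init_sd: np.ndarray,
    bin_s: float = 0.02,
) -> List[np.ndarray]:
    """Adapt a session-ordered stream of blocks with EW running statistics.

    Initial state comes from training-day statistics (the documented seed
    state for a session's first trial).
    """
    state = RollingStats.from_half_life(half_life_s, init_mean, init_sd, bin_s)
    return [state.normalize_block(b) for b in blocks]


def stack_bins(block: np.ndarray, k: int = 4) -> np.ndarray:
    """Concatenate non-overlapping windows of k bins; remainder dropped."""
    x = np.asarray(block)
    steps = x.shape[0] // k
    return x[: steps * k].reshape(steps, k * x.shape[1])


def stack_labels(frame_labels: np.ndarray, k: int = 4) -> np.ndarray:
    """Per-step majority label over each k-bin window (diagnostics)."""
    fl = np.asarray(frame_labels)
    steps = len(fl) // k
    out = np.empty(steps, dtype=int)
    for s in range(steps):
        vals, counts = np.unique(fl[s * k:(s + 1) * k], return_counts=True)
        out[s] = vals[np.argmax(counts)]
    return out


def prepare_inputs(
    trials,
    stats: Tuple[np.ndarray, np.ndarray] | None = None,
    k: int = 4,
    boxcar: int = 2,
    from_go: bool = True,
    adapt_half_life_s: float | None = None,
    bin_s: float = 0.02,
) -> List[np.ndarray]:
    """Full decoder-input pipeline: block → causal smooth → normalize → stack.

    With ``adapt_half_life_s`` set, rolling adaptation (initialized from
    ``stats``) replaces frozen z-scoring; trials must be in session order.
    """
    blocks = [causal_boxcar(make_block(t), boxcar) for t in trials]
    if stats is None:
        stats = column_stats(blocks)
    if adapt_half_life_s is not None:
        normed = rolling_adapt(blocks, adapt_half_life_s, stats[0], stats[1], bin_s)
    else:
        normed = block_zscore(blocks, stats)
    out = []
    for t, b in zip(trials, normed):
        if from_go:
            b = b[t.go_bin:]
        out.append(stack_bins(b, k))
    return out


def training_stats(trials, boxcar: int = 2) -> Tuple[np.ndarray, np.ndarray]:
    """Frozen normalization statistics from a set of training trials."""
    return column_stats([causal_boxcar(make_block(t), boxcar) for t in trials])
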