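"""Instructed-delay analyses: PSTHs, naive Bayes classification, ANOVA
tuning maps and fraction-of-variance-accounted-for (FVAF) heatmaps.

Trials are aligned to the go cue.  Classification uses Gaussian naive Bayes
on windowed per-electrode mean rates with leave-one-out cross-validation;
confidence intervals come from percentile bootstrap over trials.  Tuning
significance is one-way fixed-effects ANOVA on 800 ms binned rates at a
fixed threshold (reported per bin); FVAF is the between-condition sum of
squares over the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.naive_bayes import GaussianNB

from .features import gaussian_smooth
from .simulator import TrialRecord

VAR_FLOOR = 1e-6


@dataclass
class ConditionDataset:
    """Trials grouped by condition label, go-cue aligned, 20 ms bins."""

    trials: Dict[str, List[TrialRecord]]
    bin_s: float = 0.02

    def __post_init__(self):
        if len(self.trials) < 2:
            raise ValueError("need at least two conditions")
        dims = {t.tx.shape[1] for ts in self.trials.values() for t in ts}
        if len(dims) != 1:
            raise ValueError("inconsistent electrode count across trials")
        self.n_electrodes = dims.pop()

    @classmethod
    def from_trials(cls, trials: Sequence[TrialRecord], bin_s: float = 0.02):
        groups: Dict[str, List[TrialRecord]] = {}
        for t in trials:
            groups.setdefault(t.condition or t.sentence, []).append(t)
        return cls(groups, bin_s)

    @property
    def conditions(self) -> List[str]:
        return sorted(self.trials)

    def aligned_rates(self, condition: str) -> np.ndarray:
        """(n_trials, bins, electrodes) TX rates in Hz, go-cue aligned,
        truncated to the shortest trial of the condition."""
        ts = self.trials[condition]
        n = min(t.n_bins for t in ts)
        return np.stack([t.tx[:n] for t in ts]) / self.bin_s

    def window_means(self, start_s: float, stop_s: float,
                     relative_to_go: bool = True) -> Tuple[np.ndarray, np.ndarray]:
        """Per-trial per-electrode mean rate in a window; returns (X, y)."""
        X, y = [], []
        for c in self.conditions:
            for t in self.trials[c]:
                go = t.go_bin if relative_to_go else 0
                b0 = go + int(round(start_s / self.bin_s))
                b1 = go + int(round(stop_s / self.bin_s))
                if b0 < 0 or b1 > t.n_bins:
                    raise ValueError(
                        f"window [{start_s}, {stop_s}]s exceeds trial length")
                X.append(t.tx[b0:b1].mean(axis=0) / self.bin_s)
                y.append(c)
        return np.asarray(X), np.asarray(y)


def psth(
    dataset: ConditionDataset,
    condition: str,
    smooth_sd_ms: float = 80.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-averaged smoothed rate with bootstrap 95% CI.

    Returns (mean, lo, hi), each (bins, electrodes).  With a single trial
    the CI collapses onto the point estimate.
    """
    rates = dataset.aligned_rates(condition)
    sm = np.stack([gaussian_smooth(r, smooth_sd_ms,
                                   dataset.bin_s * 1000) for r in rates])
    mean = sm.mean(axis=0)
    n = sm.shape[0]
    if n == 1:
        return mean, mean.copy(), mean.copy()
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot,) + mean.shape)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = sm[idx].mean(axis=0)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return mean, lo, hi


def _loo_correct(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-trial leave-one-out Gaussian-NB correctness (variance-floored)."""
    clf = GaussianNB(var_smoothing=VAR_FLOOR / max(X.var(), 1.0))
    pred = cross_val_predict(clf, X, y, cv=LeaveOneOut())
    return pred == y


def naive_bayes_accuracy(
    dataset: ConditionDataset,
    window_s: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[float, Tuple[float, float]]:
    """LOO-CV classification accuracy on [go, go + window_s) mean rates,
    with a bootstrap 95% CI over trials."""
    X, y = dataset.window_means(0.0, window_s)
    correct = _loo_correct(X, y)
    acc = float(correct.mean())
    rng = np.random.default_rng(seed)
    n = len(correct)
    boot = rng.integers(0, n, (n_boot, n))
    means = correct[boot].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return acc, (float(lo), float(hi))


def time_resolved_accuracy(
    dataset: ConditionDataset,
    window_ms: float = 100.0,
    step_ms: float = 20.0,
) -> pd.DataFrame:
    """Sliding-window LOO accuracy across the delay and movement epochs.

    Windows are centered on each time point (columns: time_s relative to
    go, accuracy, chance).
    """
    bin_ms = dataset.bin_s * 1000
    half = window_ms / 2000.0
    go = min(t.go_bin for ts in dataset.trials.values() for t in ts)
    n_bins = min(t.n_bins for ts in dataset.trials.values() for t in ts)
    t_lo = -go * dataset.bin_s + half
    t_hi = (n_bins - go) * dataset.bin_s - half
    times = np.arange(t_lo, t_hi + 1e-9, step_ms / 1000.0)
    rows = []
    k = len(dataset.conditions)
    for tc in times:
        X, y = dataset.window_means(tc - half, tc + half)
        rows.append({"time_s": tc, "accuracy": float(_loo_correct(X, y).mean()),
                     "chance": 1.0 / k})
    return pd.DataFrame(rows)


def _binned_rates(dataset: ConditionDataset, bin_ms: float):
    """Per-trial rates in coarse bins: (X list per bin, labels)."""
    n_bins = min(t.n_bins for ts in dataset.trials.values() for t in ts)
    width = int(round(bin_ms / 1000.0 / dataset.bin_s))
    n_coarse = n_bins // width
    X = []   # (n_trials, n_coarse, electrodes)
    y = []
    for c in dataset.conditions:
        for t in dataset.trials[c]:
            r = t.tx[: n_coarse * width] / dataset.bin_s
            X.append(r.reshape(n_coarse, width, -1).mean(axis=1))
            y.append(c)
    return np.stack(X), np.asarray(y), n_coarse


def anova_map(
    dataset: ConditionDataset,
    bin_ms: float = 800.0,
    alpha: float = 1e-5,
) -> pd.DataFrame:
    """Per-electrode tuning significance: one-way ANOVA across conditions
    of the coarse-binned rate, tested per bin at the fixed ``alpha``.

    An electrode is flagged significant if any bin is below ``alpha``
    (the number of bins tested is recorded in the ``n_bins`` column).
    """
    X, y, n_coarse = _binned_rates(dataset, bin_ms)
    conds = dataset.conditions
    rows = []
    for e in range(X.shape[2]):
        pmin = 1.0
        pvals = []
        for b in range(n_coarse):
            groups = [X[y == c, b, e] for c in conds]
            if any(len(g) < 2 for g in groups):
                raise ValueError("ANOVA needs >= 2 trials per condition")
            f, pv = sstats.f_oneway(*groups)
            pv = 1.0 if np.isnan(pv) else pv
            pvals.append(pv)
            pmin = min(pmin, pv)
        rows.append({"electrode": e, "p_min": pmin,
                     "significant": pmin < alpha, "n_bins": n_coarse,
                     "p_bins": pvals})
    return pd.DataFrame(rows)


def fvaf(values: np.ndarray, labels: np.ndarray) -> float:
    """SS_between / SS_total of scalar values grouped by condition label."""
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for c in np.unique(labels):
        g = values[labels == c]
        ss_between += len(g) * (g.mean() - grand) ** 2
    return float(ss_between / ss_total)


def fvaf_map(dataset: ConditionDataset, bin_ms: float = 800.0) -> pd.DataFrame:
    """Per-electrode FVAF of coarse-binned rates (max across bins, with the
    per-bin profile retained)."""
    X, y, n_coarse = _binned_rates(dataset, bin_ms)
    rows = []
    for e in range(X.shape[2]):
        per_bin = [fvaf(X[:, b, e], y) for b in range(n_coarse)]
        rows.append({"electrode": e, "fvaf": max(per_bin),
                     "fvaf_bins": per_bin})
    return pd.DataFrame(rows)


def tuning_map_to_csv(anova_df: pd.DataFrame, fvaf_df: pd.DataFrame, path,
                      grid_shape: Optional[Tuple[int, int]] = None) -> None:
    """Merged TuningMap export: electrode, row, col, p, significant, FVAF."""
    df = anova_df[["electrode", "p_min", "significant"]].merge(
        fvaf_df[["electrode", "fvaf"]], on="electrode")
    if grid_shape is not None:
        df["row"] = df["electrode"] // grid_shape[1]
        df["col"] = df["electrode"] % grid_shape[1]
    df.to_csv(path, index=False)
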