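"""Design-consideration sweeps and across-day stability, on synthetic data.

Four analyses: word error rate versus electrode count (with the log-linear
per-doubling factor), versus language-model vocabulary size (reprocessing
fixed posteriorgrams), versus the number of evaluation-day training
sentences (day-to-day generalization), and the day-pair Pearson correlation
of word neural patterns.  Every sweep is reproducible from its manifest
(config + seeds), and test sentences never appear in training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ctc import greedy_decode
from .decode import LexiconTrie, beam_search_decode
from .features import prepare_inputs, training_stats
from .lm import restrict_vocab
from .metrics import batch_wer
from .phonemes import Lexicon, PhonemeInventory
from .pipeline import (PipelineConfig, build_lm, build_world, child_seed,
                       fit_decoder, simulate_split)
from .rnn import DecoderConfig, GRUDecoder, TrainConfig, train_decoder
from .simulator import SimConfig, TrialRecord


@dataclass
class SweepResult:
    kind: str
    table: pd.DataFrame              # one row per (value, seed)
    summary: pd.DataFrame            # mean/s.d. per value
    fit: Dict = field(default_factory=dict)
    manifest: Dict = field(default_factory=dict)

    @classmethod
    def build(cls, kind: str, rows: List[dict], fit: Dict | None = None,
              manifest: Dict | None = None) -> "SweepResult":
        table = pd.DataFrame(rows)
        summary = (table.groupby("value")["metric"]
                   .agg(["mean", "std", "count"]).reset_index())
        return cls(kind, table, summary, fit or {}, manifest or {})


def _subset_trials(trials: Sequence[TrialRecord], electrodes: np.ndarray):
    out = []
    for t in trials:
        out.append(dataclasses.replace(
            t, tx=t.tx[:, electrodes], sbp=t.sbp[:, electrodes]))
    return out


def electrode_sweep(
    counts: Sequence[int],
    n_seeds: int = 3,
    seed: int = 0,
    cfg: Optional[PipelineConfig] = None,
) -> SweepResult:
    """Retrain the decoder on nested electrode subsets and fit the
    log-linear WER-vs-count relationship.

    Within a seed, subsets are nested (the first ``count`` channels of one
    random permutation) to reduce subset-sampling variance.  The fit is
    ``log(WER) = a + b log2(count)``; ``factor = 2**b`` is the reported
    per-doubling WER multiplier.
    """
    cfg = cfg or PipelineConfig()
    counts = sorted(counts)
    if counts[-1] > cfg.n_electrodes:
        raise ValueError("count exceeds simulated electrode number")
    rows = []
    inv, lexicon, table, tuning, tr_s, te_s = build_world(cfg, seed)
    lm = build_lm(cfg, lexicon, seed)
    trie = LexiconTrie(lexicon)
    for s in range(n_seeds):
        sub_seed = child_seed(seed, f"electrodes{s}")
        rng = np.random.default_rng(sub_seed)
        perm = rng.permutation(cfg.n_electrodes)
        train_trials, test_trials = simulate_split(
            cfg, tuning, table, lexicon, tr_s, te_s, sub_seed)
        for count in counts:
            keep = perm[:count]
            sub_tr = _subset_trials(train_trials, keep)
            sub_te = _subset_trials(test_trials, keep)
            dec, stats, _, (x_te, y_te, d_te), _ = fit_decoder(
                cfg, inv, sub_tr, sub_te, child_seed(sub_seed, f"n{count}"))
            posts = [dec.posteriorgram(x, d) for x, d in zip(x_te, d_te)]
            hyps = [beam_search_decode(p, lm, lexicon,
                                       beam_width=cfg.beam_width,
                                       trie=trie).sentence for p in posts]
            wer = batch_wer(hyps, te_s)
            rows.append({"value": count, "seed": s, "metric": wer})
    df = pd.DataFrame(rows)
    mean_wer = df.groupby("value")["metric"].mean()
    total_ref_words = sum(len(s.split()) for s in te_s)
    floor = 0.5 / total_ref_words   # log-fit guard when a sweep point is exact
    y = np.log(np.maximum(mean_wer.to_numpy(), floor))
    x = np.log2(mean_wer.index.to_numpy(dtype=float))
    b, a = np.polyfit(x, y, 1)
    fit = {"a": float(a), "b": float(b), "factor_per_doubling": float(2.0**b)}
    return SweepResult.build("electrodes", rows, fit,
                             {"seed": seed, "counts": list(counts)})


def vocab_size_sweep(
    posteriors: Sequence[np.ndarray],
    references: Sequence[str],
    lm,
    lexicon: Lexicon,
    sizes: Sequence[int],
    true_words: Sequence[str],
    beam_width: int = 24,
    distractor_seed: int = 0,
) -> SweepResult:
    """Decode identical posteriorgrams with LMs of growing vocabulary.

    The true word set is always retained; additional words are the most
    frequent remainder of the LM vocabulary.  Requires ``lm``/``lexicon``
    to already contain the larger vocabulary (see
    :func:`speechbci.corpus.add_distractor_words`).
    """
    rows = []
    true_words = [w.upper() for w in true_words]
    ranked = sorted((w for w in lm.decode_vocab if w not in true_words),
                    key=lambda w: (-lm.unigram_count(w), w))
    for size in sorted(sizes):
        if size < len(true_words):
            raise ValueError("size smaller than the true word set")
        words = true_words + ranked[: size - len(true_words)]
        sub_lm = restrict_vocab(lm, words)
        trie = LexiconTrie(lexicon, [w for w in words if w in lexicon])
        hyps = [beam_search_decode(p, sub_lm, lexicon, beam_width=beam_width,
                                   trie=trie).sentence for p in posteriors]
        wer = batch_wer(hyps, list(references))
        rows.append({"value": size, "seed": 0, "metric": wer})
    return SweepResult.build("vocab", rows,
                             manifest={"sizes": list(sizes)})


def training_size_sweep(
    new_day_counts: Sequence[int],
    n_seeds: int = 2,
    seed: int = 0,
    cfg: Optional[PipelineConfig] = None,
) -> SweepResult:
    """WER on a new day as a function of new-day training sentences.

    Prior days contribute all their data; the evaluation day contributes
    0..n sentences.  With zero new-day sentences the new day's input layer
    is initialized by copying the most recent prior day's (flagged in the
    manifest as the zero-shot mechanism).
    """
    cfg = cfg or PipelineConfig()
    if cfg.n_days < 2:
        cfg = PipelineConfig(**{**dataclasses.asdict(cfg),
                                "n_days": 2, "sim": cfg.sim})  # pragma: no cover
    rows = []
    inv, lexicon, table, tuning, tr_s, te_s = build_world(cfg, seed)
    lm = build_lm(cfg, lexicon, seed)
    trie = LexiconTrie(lexicon)
    new_day = cfg.n_days - 1
    for s in range(n_seeds):
        sub_seed = child_seed(seed, f"trainsize{s}")
        train_trials, test_trials = simulate_split(
            cfg, tuning, table, lexicon, tr_s, te_s, sub_seed)
        prior = [t for t in train_trials if t.day < new_day]
        new = [t for t in train_trials if t.day == new_day]
        test_new = [t for t in test_trials if t.day == new_day]
        te_s_new = [t.sentence for t in test_new]
        for count in sorted(new_day_counts):
            use = prior + new[:count]
            dec, stats, _, (x_te, y_te, d_te), _ = fit_decoder(
                cfg, inv, use, test_new, child_seed(sub_seed, f"c{count}"))
            if count == 0:
                dec.clone_day_layer(new_day - 1, new_day)
            posts = [dec.posteriorgram(x, d) for x, d in zip(x_te, d_te)]
            hyps = [beam_search_decode(p, lm, lexicon,
                                       beam_width=cfg.beam_width,
                                       trie=trie).sentence for p in posts]
            rows.append({"value": count, "seed": s,
                         "metric": batch_wer(hyps, te_s_new)})
    return SweepResult.build(
        "trainsize", rows,
        manifest={"seed": seed, "zero_shot": "copy most recent prior day layer"})


def day_layer_ablation(
    seed: int = 0,
    cfg: Optional[PipelineConfig] = None,
) -> Dict[str, float]:
    """Day-specific input layers versus a shared input layer under a planted
    across-day channel permutation.

    Three decoders on a 2-day dataset whose second day has every channel
    relabeled: (1) day-specific input layers, (2) a single shared input
    layer with the day labels hidden, (3) a single-day reference trained
    and tested on day 0 only.  Returns the three held-out PERs.
    """
    if cfg is None:
        cfg = PipelineConfig(
            n_train=200, n_test=40, n_days=2, n_electrodes=32,
            hidden=48, n_layers=1, epochs=20,
            sim=SimConfig(permute_frac=1.0, day_offset_sd_hz=4.0))
    inv, lexicon, table, tuning, tr_s, te_s = build_world(cfg, seed)
    train_trials, test_trials = simulate_split(
        cfg, tuning, table, lexicon, tr_s, te_s, seed)
    _, _, _, _, hist = fit_decoder(cfg, inv, train_trials, test_trials, seed)
    shared_cfg = dataclasses.replace(cfg, n_days=1, sim=cfg.sim)
    tr0 = [dataclasses.replace(t, day=0) for t in train_trials]
    te0 = [dataclasses.replace(t, day=0) for t in test_trials]
    _, _, _, _, hist_shared = fit_decoder(shared_cfg, inv, tr0, te0, seed)
    tr_d0 = [t for t in train_trials if t.day == 0]
    te_d0 = [t for t in test_trials if t.day == 0]
    _, _, _, _, hist_single = fit_decoder(shared_cfg, inv, tr_d0, te_d0, seed)
    return {
        "per_day_layers": float(hist.valid_per[-1]),
        "per_shared": float(hist_shared.valid_per[-1]),
        "per_single_day": float(hist_single.valid_per[-1]),
    }


def day_similarity(
    trials: Sequence[TrialRecord],
    diagnostic_words: Optional[Sequence[str]] = None,
    epoch_s: Tuple[float, float] = (0.0, 1.0),
    bin_s: float = 0.02,
) -> pd.DataFrame:
    """Day-pair Pearson r of trial-averaged word activity patterns.

    Per day and word (condition), the movement-epoch mean rate per
    electrode; a day's pattern is the concatenated word x electrode matrix,
    correlated between day pairs over words common to both.
    """
    words = set(diagnostic_words) if diagnostic_words else None
    per_day: Dict[int, Dict[str, List[np.ndarray]]] = {}
    for t in trials:
        label = t.condition or t.sentence
        if words is not None and label not in words:
            continue
        b0 = t.go_bin + int(round(epoch_s[0] / bin_s))
        b1 = min(t.n_bins, t.go_bin + int(round(epoch_s[1] / bin_s)))
        vec = t.tx[b0:b1].mean(axis=0) / bin_s
        per_day.setdefault(t.day, {}).setdefault(label, []).append(vec)
    days = sorted(per_day)
    avg = {d: {w: np.mean(v, axis=0) for w, v in per_day[d].items()}
           for d in days}
    rows = []
    for i, d1 in enumerate(days):
        for d2 in days[i:]:
            common = sorted(set(avg[d1]) & set(avg[d2]))
            if len(common) < 2:
                continue
            a = np.concatenate([avg[d1][w] for w in common])
            b = np.concatenate([avg[d2][w] for w in common])
            r = float(np.corrcoef(a, b)[0, 1])
            rows.append({"day_a": d1, "day_b": d2, "r": r,
                         "n_words": len(common)})
    return pd.DataFrame(rows)
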