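"""End-to-end convenience wiring: simulate → preprocess → train → decode.

This is the glue the sweeps, the command-line interface and the worked
examples share.  Defaults describe the standard synthetic study: a 50-word
vocabulary, 300 training / 50 test sentences on a 64-electrode array, and a
deliberately small recurrent decoder that trains in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import corpus as corpus_mod
from .articulation import ArticulatoryFeatureTable
from .ctc import greedy_decode
from .decode import LexiconTrie, beam_search_decode, decode_no_lm
from .features import prepare_inputs, training_stats
from .lm import TrigramLM, train_trigram
from .metrics import batch_per, batch_wer
from .phonemes import Lexicon, PhonemeInventory, sentence_to_labels
from .rnn import DecoderConfig, GRUDecoder, TrainConfig, train_decoder
from .simulator import SimConfig, TrialRecord, make_tuning, synthesize_dataset


def child_seed(seed: int, name: str) -> int:
    """Named substream of a global seed (stable, < 2**31)."""
    import zlib
    return (seed * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    n_train: int = 300
    n_test: int = 50
    n_electrodes: int = 64
    n_days: int = 1
    stack: int = 4
    epochs: int = 30
    hidden: int = 96
    n_layers: int = 2
    batch_size: int = 32
    lr: float = 4e-3
    beam_width: int = 24
    lm_corpus_size: int = 2000
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        self.sim = dataclasses.replace(
            self.sim, n_electrodes=self.n_electrodes, n_days=self.n_days)


@dataclass
class PipelineResult:
    decoder: GRUDecoder
    lexicon: Lexicon
    lm: TrigramLM
    stats: Tuple[np.ndarray, np.ndarray]
    posteriors: List[np.ndarray]          # test-set posteriorgrams
    test_sentences: List[str]
    test_days: List[int]
    per: float                            # greedy PER on the test set
    wer_lm: float                         # beam + trigram WER
    wer_nolm: float                       # greedy nearest-word baseline WER
    hyp_lm: List[str]
    hyp_nolm: List[str]
    history: object


def build_world(cfg: PipelineConfig, seed: int):
    """Lexicon, feature table, tuning model and train/test sentences."""
    inv = PhonemeInventory()
    lexicon = corpus_mod.default_lexicon(inv)
    table = ArticulatoryFeatureTable.default()
    table.validate(inv)
    tuning = make_tuning(cfg.n_electrodes, table, cfg.sim,
                         seed=child_seed(seed, "tuning"))
    train_sents = corpus_mod.generate_sentences(
        cfg.n_train, child_seed(seed, "train_sents"))
    test_sents = corpus_mod.generate_sentences(
        cfg.n_test, child_seed(seed, "test_sents"), exclude=train_sents)
    return inv, lexicon, table, tuning, train_sents, test_sents


def simulate_split(cfg, tuning, table, lexicon, train_sents, test_sents, seed,
                   mode: str = "vocal"):
    days = list(range(cfg.n_days))
    train_trials, _ = synthesize_dataset(
        train_sents, days, tuning, table, lexicon,
        seed=child_seed(seed, "train_data"), mode=mode)
    test_trials, _ = synthesize_dataset(
        test_sents, days, tuning, table, lexicon,
        seed=child_seed(seed, "test_data"), mode=mode)
    return train_trials, test_trials


def fit_decoder(cfg: PipelineConfig, inv: PhonemeInventory,
                train_trials, test_trials, seed: int,
                log: bool = False):
    """Preprocess both splits with training statistics and train the GRU."""
    stats = training_stats(train_trials)
    x_tr = prepare_inputs(train_trials, stats, k=cfg.stack)
    x_te = prepare_inputs(test_trials, stats, k=cfg.stack)
    y_tr = [list(t.labels) for t in train_trials]
    y_te = [list(t.labels) for t in test_trials]
    d_tr = [t.day for t in train_trials]
    d_te = [t.day for t in test_trials]
    dec = GRUDecoder(DecoderConfig(
        n_layers=cfg.n_layers, hidden=cfg.hidden,
        input_dim=x_tr[0].shape[1], n_days=cfg.n_days,
        seed=child_seed(seed, "init")))
    hist = train_decoder(
        dec, x_tr, y_tr, d_tr,
        TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
                    seed=child_seed(seed, "sgd"), log=log,
                    eval_every=max(1, cfg.epochs)),
        blank=inv.blank_index,
        valid=(x_te, y_te, d_te))
    return dec, stats, (x_tr, y_tr, d_tr), (x_te, y_te, d_te), hist


def build_lm(cfg: PipelineConfig, lexicon: Lexicon, seed: int) -> TrigramLM:
    text = corpus_mod.generate_corpus(cfg.lm_corpus_size,
                                      child_seed(seed, "lm_corpus"))
    return train_trigram(text, vocab=lexicon.words)


def run_pipeline(seed: int, cfg: Optional[PipelineConfig] = None,
                 log: bool = False, mode: str = "vocal") -> PipelineResult:
    """The full synthetic study at one seed."""
    cfg = cfg or PipelineConfig()
    inv, lexicon, table, tuning, tr_s, te_s = build_world(cfg, seed)
    train_trials, test_trials = simulate_split(
        cfg, tuning, table, lexicon, tr_s, te_s, seed, mode)
    dec, stats, _, (x_te, y_te, d_te), hist = fit_decoder(
        cfg, inv, train_trials, test_trials, seed, log)
    lm = build_lm(cfg, lexicon, seed)
    trie = LexiconTrie(lexicon)
    posts = [dec.posteriorgram(x, d) for x, d in zip(x_te, d_te)]
    hyp_phonemes = [greedy_decode(p, inv.blank_index) for p in posts]
    per = batch_per(hyp_phonemes, y_te)
    hyp_lm = [beam_search_decode(p, lm, lexicon, beam_width=cfg.beam_width,
                                 trie=trie).sentence for p in posts]
    hyp_nolm = [" ".join(decode_no_lm(p, lexicon)) for p in posts]
    wer_lm = batch_wer(hyp_lm, te_s)
    wer_nolm = batch_wer(hyp_nolm, te_s)
    return PipelineResult(dec, lexicon, lm, stats, posts, te_s, d_te,
                          per, wer_lm, wer_nolm, hyp_lm, hyp_nolm, hist)
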