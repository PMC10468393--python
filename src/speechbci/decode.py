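"""Word decoding from phoneme posteriorgrams: CTC prefix beam search with
trigram shallow fusion, plus an exhaustive oracle.

The search walks a lexicon trie over phoneme prefixes, maintaining separate
blank / non-blank path probabilities per prefix.  A word completes when the
SIL token is consumed at a trie node that ends one or more pronunciations
(the decoder is trained to emit SIL at every word end); the language-model
log-probability is added at that point (shallow fusion).  Hypotheses are
keyed by (word history, phoneme prefix), so with an unbounded beam the
acoustic score of a word sequence is the exact CTC marginal of its phoneme
expansion — which is what :func:`exhaustive_decode` computes directly, word
sequence by word sequence, with the forward algorithm.

Scores decompose as::

    total = acoustic_weight * acoustic + lm_weight * lm + n_words * insertion_bonus

Ties are broken lexicographically on the word sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ctc import ctc_forward_logprob, greedy_decode
from .lm import EOS, RestrictedLM, TrigramLM
from .metrics import levenshtein
from .phonemes import Lexicon, PhonemeInventory

NEG_INF = -np.inf


@dataclass
class DecodeResult:
    words: List[str]
    phonemes: List[int]              # phoneme indices of the best expansion
    score: float                     # documented identity, see module docstring
    acoustic: float                  # log CTC marginal
    lm_score: float                  # log p(words, </s>)
    n_words: int
    beam_stats: Dict = field(default_factory=dict)

    @property
    def sentence(self) -> str:
        return " ".join(self.words)


class LexiconTrie:
    """Phoneme-index trie over pronunciations; words complete via SIL."""

    def __init__(self, lexicon: Lexicon, words: Optional[Sequence[str]] = None):
        inv = lexicon.inventory
        self.inventory = inv
        self.children: List[Dict[int, int]] = [{}]
        self.words_at: List[List[str]] = [[]]
        words = sorted(w.upper() for w in (words or lexicon.words))
        for w in words:
            for pron in lexicon.pronunciations(w):
                node = 0
                for ph in pron:
                    i = inv.index(ph)
                    nxt = self.children[node].get(i)
                    if nxt is None:
                        nxt = len(self.children)
                        self.children[node][i] = nxt
                        self.children.append({})
                        self.words_at.append([])
                    node = nxt
                if w not in self.words_at[node]:
                    self.words_at[node].append(w)
        for lst in self.words_at:
            lst.sort()
        self.n_words = len(words)


def _lse(a: float, b: float) -> float:
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    return float(np.logaddexp(a, b))


def beam_search_decode(
    posteriorgram: np.ndarray,
    lm: TrigramLM | RestrictedLM,
    lexicon: Lexicon,
    beam_width: Optional[int] = 64,
    acoustic_weight: float = 1.0,
    lm_weight: float = 1.0,
    insertion_bonus: float = 0.0,
    trie: Optional[LexiconTrie] = None,
) -> DecodeResult:
    """Lexicon-constrained CTC prefix beam search with LM shallow fusion.

    ``beam_width=None`` disables pruning (exact search; exponential, for
    small instances only).  Deterministic: ties break lexicographically.
    """
    if beam_width is not None and beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    inv = lexicon.inventory
    if trie is None:
        vocab = [w for w in lexicon.words if w in set(lm.decode_vocab)]
        if not vocab:
            raise ValueError("empty decoding lexicon (lexicon ∩ LM vocab)")
        trie = LexiconTrie(lexicon, vocab)
    lp = np.log(np.clip(np.asarray(posteriorgram, dtype=float), 1e-300, None))
    T = lp.shape[0]
    sil, blank = inv.sil_index, inv.blank_index

    # key: (words tuple, phoneme prefix tuple) -> [pb, pnb, node, lm_logp]
    beam: Dict[tuple, list] = {((), ()): [0.0, NEG_INF, 0, 0.0]}
    max_beam = 0

    def upd(store, key, node, lms, pb_add=NEG_INF, pnb_add=NEG_INF):
        e = store.get(key)
        if e is None:
            e = [NEG_INF, NEG_INF, node, lms]
            store[key] = e
        e[0] = _lse(e[0], pb_add)
        e[1] = _lse(e[1], pnb_add)

    for t in range(T):
        new: Dict[tuple, list] = {}
        for (words, prefix), (pb, pnb, node, lms) in beam.items():
            tot = _lse(pb, pnb)
            # stay on this prefix via blank
            upd(new, (words, prefix), node, lms, pb_add=tot + lp[t, blank])
            last = prefix[-1] if prefix else None
            # stay via repeated emission of the last token
            if last is not None and pnb > NEG_INF:
                upd(new, (words, prefix), node, lms, pnb_add=pnb + lp[t, last])
            # extend within the current word
            for c, child in trie.children[node].items():
                base = pb if c == last else tot
                if base == NEG_INF:
                    continue
                upd(new, (words, prefix + (c,)), child, lms,
                    pnb_add=base + lp[t, c])
            # complete word(s) by consuming SIL
            if trie.words_at[node]:
                base = pb if last == sil else tot
                if base > NEG_INF:
                    for w in trie.words_at[node]:
                        upd(new, (words + (w,), prefix + (sil,)), 0,
                            lms + lm.logp(w, list(words)),
                            pnb_add=base + lp[t, sil])
        if beam_width is not None and len(new) > beam_width:
            def rank(item):
                (words, prefix), (pb, pnb, node, lms) = item
                return (-(acoustic_weight * _lse(pb, pnb) + lm_weight * lms
                          + insertion_bonus * len(words)), words, prefix)
            items = sorted(new.items(), key=rank)[:beam_width]
            new = dict(items)
        beam = new
        max_beam = max(max_beam, len(beam))

    # finalize: complete-word hypotheses only, grouped by word sequence
    finals: Dict[tuple, float] = {}
    best_prefix: Dict[tuple, tuple] = {}
    best_prefix_ac: Dict[tuple, float] = {}
    for (words, prefix), (pb, pnb, node, lms) in beam.items():
        if node != 0 or not words:
            continue
        ac = _lse(pb, pnb)
        if ac == NEG_INF:
            continue
        finals[words] = _lse(finals[words], ac) if words in finals else ac
        if ac > best_prefix_ac.get(words, NEG_INF):
            best_prefix_ac[words] = ac
            best_prefix[words] = prefix

    if not finals:
        return DecodeResult([], [], NEG_INF, NEG_INF, NEG_INF, 0,
                            {"max_beam": max_beam, "empty": True})

    scored = []
    for words, ac in finals.items():
        lmtot = sum(lm.logp(w, list(words[:i])) for i, w in enumerate(words))
        lmtot += lm.logp(EOS, list(words))
        total = (acoustic_weight * ac + lm_weight * lmtot
                 + insertion_bonus * len(words))
        scored.append((total, words, ac, lmtot))
    scored.sort(key=lambda x: (-x[0], x[1]))
    total, words, ac, lmtot = scored[0]
    return DecodeResult(list(words), list(best_prefix[words]), total, ac,
                        lmtot, len(words),
                        {"max_beam": max_beam, "n_final": len(scored)})


def exhaustive_decode(
    posteriorgram: np.ndarray,
    lm: TrigramLM | RestrictedLM,
    lexicon: Lexicon,
    max_words: int = 3,
    acoustic_weight: float = 1.0,
    lm_weight: float = 1.0,
    insertion_bonus: float = 0.0,
) -> DecodeResult:
    """Enumerate every word sequence up to ``max_words`` and score it by the
    full CTC marginal (forward algorithm, summed over pronunciation
    variants) plus the LM.  The argmax is the exact decode; test oracle for
    :func:`beam_search_decode`.
    """
    inv = lexicon.inventory
    lp = np.log(np.clip(np.asarray(posteriorgram, dtype=float), 1e-300, None))
    vocab = sorted(w for w in lexicon.words if w in set(lm.decode_vocab))
    if not vocab:
        raise ValueError("empty decoding lexicon")
    sil, blank = inv.sil_index, inv.blank_index

    best: Optional[Tuple[float, tuple, float, float, list]] = None
    for n in range(1, max_words + 1):
        for words in itertools.product(vocab, repeat=n):
            expansions = []
            for prons in itertools.product(
                    *[lexicon.pronunciations(w) for w in words]):
                target: List[int] = []
                for pron in prons:
                    target.extend(inv.index(p) for p in pron)
                    target.append(sil)
                expansions.append(target)
            acs = [ctc_forward_logprob(lp, tgt, blank) for tgt in expansions]
            finite = [a for a in acs if a > NEG_INF]
            if not finite:
                continue
            ac = float(np.logaddexp.reduce(finite))
            lmtot = sum(lm.logp(w, list(words[:i])) for i, w in enumerate(words))
            lmtot += lm.logp(EOS, list(words))
            total = acoustic_weight * ac + lm_weight * lmtot \
                + insertion_bonus * n
            key = (total, words)
            if best is None or total > best[0] + 1e-12 or (
                    abs(total - best[0]) <= 1e-12 and words < best[1]):
                phon = expansions[int(np.argmax(acs))]
                best = (total, words, ac, lmtot, phon)
    if best is None:
        return DecodeResult([], [], NEG_INF, NEG_INF, NEG_INF, 0)
    total, words, ac, lmtot, phon = best
    return DecodeResult(list(words), phon, total, ac, lmtot, len(words))


def decode_no_lm(
    posteriorgram: np.ndarray,
    lexicon: Lexicon,
) -> List[str]:
    """Language-model-free baseline: greedy phoneme decode, split on SIL,
    and map each segment to the nearest lexicon pronunciation by phoneme
    edit distance (ties lexicographic)."""
    inv = lexicon.inventory
    seq = greedy_decode(np.asarray(posteriorgram), inv.blank_index)
    segments: List[List[int]] = []
    cur: List[int] = []
    for i in seq:
        if i == inv.sil_index:
            if cur:
                segments.append(cur)
                cur = []
        else:
            cur.append(i)
    if cur:
        segments.append(cur)
    prons = []
    for w in lexicon.words:
        for pron in lexicon.pronunciations(w):
            prons.append((w, [inv.index(p) for p in pron]))
    prons.sort()
    out: List[str] = []
    for seg in segments:
        best_w, best_d = None, None
        for w, pron in prons:
            d = levenshtein(seg, pron)
            if best_d is None or d < best_d:
                best_w, best_d = w, d
        out.append(best_w)
    return out
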