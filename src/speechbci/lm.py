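"""Trigram language model with interpolated absolute-discount backoff.

A single discount ``D`` (default 0.75) is subtracted from every observed
n-gram count and the freed mass is redistributed through the lower order:

    p3(w | u, v) = max(c(uvw) - D, 0) / c(uv) + gamma(uv) * p2(w | v)
    p2(w | v)    = max(c(vw)  - D, 0) / c(v)  + gamma(v)  * p1(w)
    p1(w)        = max(c(w)   - D, 0) / N     + gamma()   * 1 / |V|

with ``gamma(ctx) = D * N1+(ctx .) / c(ctx)`` (the number of distinct
continuations of the context).  Every in-vocabulary word therefore has
strictly positive probability in every context, and each conditional sums
to one over the vocabulary plus the sentence-end token.

Out-of-vocabulary corpus tokens are mapped to ``<unk>``, which takes part
in normalization but is excluded from decoding vocabularies.  Models can be
restricted to a sub-vocabulary (renormalized on the fly) and serialized in
ARPA text format.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .phonemes import tokenize

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"


@dataclass
class TrigramLM:
    vocab: List[str]                     # words incl. EOS and (maybe) UNK
    discount: float
    c1: Counter = field(default_factory=Counter)
    c2: Counter = field(default_factory=Counter)
    c3: Counter = field(default_factory=Counter)
    n1_after_1: Counter = field(default_factory=Counter)   # distinct w after (v,)
    n1_after_2: Counter = field(default_factory=Counter)   # distinct w after (u,v)
    n_tokens: int = 0

    # ------------------------------------------------------------------ queries
    @property
    def decode_vocab(self) -> List[str]:
        return [w for w in self.vocab if w not in (EOS, UNK)]

    def _map(self, w: str) -> str:
        return w if w in self._vset else UNK

    def __post_init__(self):
        self._vset = set(self.vocab)

    def p1(self, w: str) -> float:
        V = len(self.vocab)
        n1 = len(self.c1)
        gamma = self.discount * n1 / self.n_tokens
        return max(self.c1[w] - self.discount, 0.0) / self.n_tokens + gamma / V

    def p2(self, w: str, v: str) -> float:
        cv = self.c1[v] if v != BOS else self._bos_count
        if cv == 0:
            return self.p1(w)
        gamma = self.discount * self.n1_after_1[(v,)] / cv
        return max(self.c2[(v, w)] - self.discount, 0.0) / cv + gamma * self.p1(w)

    def p3(self, w: str, u: str, v: str) -> float:
        cuv = self.c2[(u, v)]
        if cuv == 0:
            return self.p2(w, v)
        gamma = self.discount * self.n1_after_2[(u, v)] / cuv
        return (max(self.c3[(u, v, w)] - self.discount, 0.0) / cuv
                + gamma * self.p2(w, v))

    def prob(self, w: str, context: Sequence[str]) -> float:
        """p(w | last two context words); BOS-padded at sentence start."""
        w = self._map(w) if w != EOS else w
        ctx = [BOS, BOS] + [self._map(t) for t in context if t != BOS]
        u, v = ctx[-2], ctx[-1]
        return self.p3(w, u, v)

    def logp(self, w: str, context: Sequence[str]) -> float:
        return math.log(self.prob(w, context))

    def sentence_logp(self, sentence: str) -> Tuple[float, int]:
        words = tokenize(sentence)
        ctx: List[str] = []
        total = 0.0
        for w in words:
            total += self.logp(w, ctx)
            ctx.append(w)
        total += self.logp(EOS, ctx)
        return total, len(words) + 1

    def perplexity(self, sentences: Iterable[str]) -> float:
        lp, n = 0.0, 0
        for s in sentences:
            l, k = self.sentence_logp(s)
            lp += l
            n += k
        return math.exp(-lp / n)

    def unigram_count(self, w: str) -> int:
        return self.c1[w]


def train_trigram(
    corpus: Sequence[str],
    vocab: Optional[Sequence[str]] = None,
    discount: float = 0.75,
) -> TrigramLM:
    """Estimate the model from tokenized sentences.

    ``vocab`` restricts the word list (OOV tokens become ``<unk>``); by
    default the vocabulary is every corpus word.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if not 0 < discount < 1:
        raise ValueError("discount must be in (0, 1)")
    sents = [tokenize(s) for s in corpus]
    sents = [s for s in sents if s]
    if not sents:
        raise ValueError("corpus contains no words")
    if vocab is None:
        vset = {w for s in sents for w in s}
        use_unk = False
    else:
        vset = {w.upper() for w in vocab}
        use_unk = True
    words = sorted(vset) + ([UNK] if use_unk else []) + [EOS]
    lm = TrigramLM(vocab=words, discount=discount)

    def m(w: str) -> str:
        return w if w in vset else UNK

    seen2: Dict[tuple, set] = {}
    seen1: Dict[tuple, set] = {}
    bos_count = 0
    for s in sents:
        toks = [m(w) for w in s] + [EOS]
        hist = [BOS, BOS]
        bos_count += 1
        for w in toks:
            lm.c1[w] += 1
            lm.n_tokens += 1
            u, v = hist[-2], hist[-1]
            lm.c2[(v, w)] += 1
            lm.c3[(u, v, w)] += 1
            seen1.setdefault((v,), set()).add(w)
            seen2.setdefault((u, v), set()).add(w)
            hist.append(w)
    lm._bos_count = bos_count
    for k, s in seen1.items():
        lm.n1_after_1[k] = len(s)
    for k, s in seen2.items():
        lm.n1_after_2[k] = len(s)
    # (v,) contexts where v == BOS need the BOS "count": c2 over (BOS, w)
    return lm


# BOS bigram context: c(BOS) = number of sentences
TrigramLM._bos_count = 0


class RestrictedLM:
    """A trigram model renormalized over a retained sub-vocabulary.

    ``p'(w | ctx) = p(w | ctx) / sum_{w' in V' + EOS} p(w' | ctx)`` —
    conditionals are recomputed on demand and cached per context.
    """

    def __init__(self, base: TrigramLM, words: Sequence[str]):
        keep = {w.upper() for w in words}
        missing = keep - set(base.vocab)
        if missing:
            raise ValueError(f"words not in base vocabulary: {sorted(missing)}")
        self.base = base
        self.vocab = sorted(keep) + [EOS]
        self._keep = keep | {EOS}
        self._z: Dict[tuple, float] = {}

    @property
    def decode_vocab(self) -> List[str]:
        return [w for w in self.vocab if w != EOS]

    def _norm(self, u: str, v: str) -> float:
        key = (u, v)
        if key not in self._z:
            self._z[key] = sum(self.base.p3(w, u, v) for w in self._keep)
        return self._z[key]

    def prob(self, w: str, context: Sequence[str]) -> float:
        if w.upper() not in self._keep and w != EOS:
            raise KeyError(f"{w!r} outside restricted vocabulary")
        ctx = [BOS, BOS] + [self.base._map(t) for t in context if t != BOS]
        u, v = ctx[-2], ctx[-1]
        return self.base.p3(w if w == EOS else self.base._map(w), u, v) \
            / self._norm(u, v)

    def logp(self, w: str, context: Sequence[str]) -> float:
        return math.log(self.prob(w, context))

    def sentence_logp(self, sentence: str) -> Tuple[float, int]:
        words = tokenize(sentence)
        ctx: List[str] = []
        total = 0.0
        for w in words:
            total += self.logp(w, ctx)
            ctx.append(w)
        total += self.logp(EOS, ctx)
        return total, len(words) + 1

    def perplexity(self, sentences: Iterable[str]) -> float:
        lp, n = 0.0, 0
        for s in sentences:
            l, k = self.sentence_logp(s)
            lp += l
            n += k
        return math.exp(-lp / n)


def restrict_vocab(lm: TrigramLM, n_or_words) -> RestrictedLM:
    """Restrict to a word list, or to the n most frequent decodable words."""
    if isinstance(n_or_words, int):
        ranked = sorted(lm.decode_vocab,
                        key=lambda w: (-lm.unigram_count(w), w))
        words = ranked[:n_or_words]
    else:
        words = list(n_or_words)
    return RestrictedLM(lm, words)


# --------------------------------------------------------------------- ARPA IO
def write_arpa(lm: TrigramLM, path) -> None:
    """Serialize in the standard ARPA n-gram interchange format.

    Probabilities are the interpolated estimates; backoff weights are the
    absolute-discount gammas, so a standard backoff evaluator reproduces
    the model on unseen n-grams.
    """
    def l10(x: float) -> str:
        return f"{math.log10(x):.6f}"

    uni = sorted(set(list(lm.vocab) + [BOS]))
    bi = sorted(lm.c2)
    tri = sorted(lm.c3)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        fh.write(f"ngram 1={len(uni)}\n")
        fh.write(f"ngram 2={len(bi)}\n")
        fh.write(f"ngram 3={len(tri)}\n\n")
        fh.write("\\1-grams:\n")
        for w in uni:
            p = 1e-99 if w == BOS else lm.p1(w)
            cv = lm.c1[w] if w != BOS else lm._bos_count
            if cv > 0 and lm.n1_after_1[(w,)] > 0:
                bow = lm.discount * lm.n1_after_1[(w,)] / cv
                fh.write(f"{l10(p)}\t{w}\t{l10(bow)}\n")
            else:
                fh.write(f"{l10(p)}\t{w}\n")
        fh.write("\n\\2-grams:\n")
        for (v, w) in bi:
            p = lm.p2(w, v)
            cuv = lm.c2[(v, w)]
            if cuv > 0 and lm.n1_after_2[(v, w)] > 0:
                bow = lm.discount * lm.n1_after_2[(v, w)] / cuv
                fh.write(f"{l10(p)}\t{v} {w}\t{l10(bow)}\n")
            else:
                fh.write(f"{l10(p)}\t{v} {w}\n")
        fh.write("\n\\3-grams:\n")
        for (u, v, w) in tri:
            fh.write(f"{l10(lm.p3(w, u, v))}\t{u} {v} {w}\n")
        fh.write("\n\\end\\\n")
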