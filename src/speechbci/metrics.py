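"""Edit-distance error rates: phoneme error rate (PER) and word error rate (WER).

PER scores the raw CTC decoder output (SIL counts as a token); WER scores
the full pipeline after language-model decoding.  Both are Levenshtein
distance (unit substitution/insertion/deletion costs) divided by reference
length; batch aggregation is total edits over total reference length, not a
mean of per-sentence rates.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .phonemes import tokenize


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Unit-cost edit distance between two token sequences."""
    a, b = list(a), list(b)
    if not a:
        return len(b)
    prev = np.arange(len(b) + 1)
    cur = np.empty(len(b) + 1, dtype=np.int64)
    for i, x in enumerate(a, start=1):
        cur[0] = i
        for j, y in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y))
        prev, cur = cur, prev
    return int(prev[len(b)])


def phoneme_error_rate(hypothesis: Sequence[int], reference: Sequence[int]) -> float:
    """Edit distance over phoneme-index sequences / reference length."""
    if len(reference) == 0:
        raise ValueError("empty reference")
    return levenshtein(list(hypothesis), list(reference)) / len(reference)


def word_error_rate(hyp_sentence: str, ref_sentence: str) -> float:
    """Word-level edit distance / reference word count (case-insensitive)."""
    ref = tokenize(ref_sentence)
    if not ref:
        raise ValueError("empty reference sentence")
    return levenshtein(tokenize(hyp_sentence), ref) / len(ref)


def _batch(pairs: List[Tuple[Sequence, Sequence]]) -> float:
    edits = sum(levenshtein(h, r) for h, r in pairs)
    total = sum(len(r) for _, r in pairs)
    if total == 0:
        raise ValueError("empty references")
    return edits / total


def batch_per(hyps: Sequence[Sequence[int]], refs: Sequence[Sequence[int]]) -> float:
    """Aggregate PER: total phoneme edits / total reference phonemes."""
    return _batch([(list(h), list(r)) for h, r in zip(hyps, refs)])


def batch_wer(hyp_sentences: Sequence[str], ref_sentences: Sequence[str]) -> float:
    """Aggregate WER: total word edits / total reference words."""
    return _batch([(tokenize(h), tokenize(r))
                   for h, r in zip(hyp_sentences, ref_sentences)])
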