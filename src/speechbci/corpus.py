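"""Synthetic sentence corpus over the bundled 50-word assistive vocabulary.

A small probabilistic phrase grammar generates simple caregiver-oriented
sentences (the style of small-vocabulary speech-BCI evaluations).  The same
grammar supplies language-model training text and decoder train/test
sentences; train/test splits are disjoint by sentence string.

For vocabulary-size sweeps, pseudo-word distractors with random
pronunciations can be appended to both lexicon and corpus.
"""

from __future__ import annotations

import importlib.resources
from typing import List, Sequence, Tuple

import numpy as np

from .phonemes import Lexicon, PhonemeInventory, load_lexicon

_STATE = ["THIRSTY", "HUNGRY", "TIRED", "GOOD", "BAD", "COMFORTABLE"]
_OBJ = ["GLASSES", "COMPUTER", "MUSIC"]
_PERSON = ["FAMILY", "NURSE"]
_LOC = ["HERE", "OUTSIDE"]
_VING = ["COMING", "GOING"]
_ADJ = ["GOOD", "BAD", "RIGHT", "CLEAN"]

_TEMPLATES: List[Tuple[str, List[List[str]]]] = [
    ("I AM {0}", [_STATE + ["HERE", "OUTSIDE"]]),
    ("I AM NOT {0}", [_STATE]),
    ("I AM VERY {0}", [_STATE]),
    ("I NEED MY {0}", [_OBJ + ["NURSE"]]),
    ("I NEED {0}", [["HELP", "MUSIC"]]),
    ("BRING MY {0} HERE", [_OBJ]),
    ("BRING MY {0}", [_OBJ]),
    ("BRING IT CLOSER", []),
    ("PLEASE BRING MY {0}", [_OBJ]),
    ("MY {0} IS {1}", [_PERSON, _LOC]),
    ("THEY ARE {0} {1}", [_VING, _LOC]),
    ("YOU ARE VERY {0}", [["GOOD", "BAD", "COMFORTABLE"]]),
    ("I FEEL VERY {0}", [["GOOD", "BAD"]]),
    ("I DO NOT FEEL {0}", [["GOOD", "BAD"]]),
    ("WHERE IS MY {0}", [_OBJ + ["FAMILY", "NURSE"]]),
    ("WHERE ARE YOU {0}", [_VING]),
    ("WHAT DO YOU NEED", []),
    ("HOW DO YOU FEEL", []),
    ("HOW ARE YOU", []),
    ("TELL MY {0} I AM {1}", [_PERSON, _STATE]),
    ("TELL MY {0} I NEED {1}", [_PERSON, ["HELP", "MUSIC"]]),
    ("I HOPE YOU ARE {0}", [["GOOD", "COMFORTABLE"]]),
    ("I HOPE YOU FEEL {0}", [["GOOD"]]),
    ("THAT IS {0}", [_ADJ]),
    ("THAT IS NOT {0}", [_ADJ]),
    ("IT IS {0}", [_ADJ]),
    ("IT IS NOT {0}", [_ADJ]),
    ("I LIKE {0}", [["MY MUSIC", "MY COMPUTER", "IT", "THAT"]]),
    ("I DO NOT LIKE {0}", [["IT", "THAT"]]),
    ("PLEASE CLEAN IT UP", []),
    ("CLEAN IT UP PLEASE", []),
    ("DO YOU HAVE MY {0}", [_OBJ]),
    ("I HAVE MY {0}", [_OBJ]),
    ("IS IT {0}", [_ADJ]),
    ("IS MY {0} {1}", [_PERSON, _LOC]),
    ("DO YOU HAVE FAITH", []),
    ("I HAVE FAITH", []),
    ("SUCCESS IS COMING", []),
    ("I HOPE THEY ARE COMING", []),
    ("WHAT IS THAT", []),
    ("YES I DO", []),
    ("NO I DO NOT", []),
]

_PREFIX = ["", "OKAY", "HELLO", "YES", "NO"]
_SINGLE = ["YES", "NO", "OKAY", "HELLO", "GOODBYE", "HELP", "PLEASE"]


def default_lexicon(inventory: PhonemeInventory | None = None) -> Lexicon:
    """The bundled 50-word CMUdict-format lexicon."""
    ref = importlib.resources.files("speechbci.data").joinpath("lexicon50.txt")
    with importlib.resources.as_file(ref) as path:
        return load_lexicon(path, inventory)


def _sample_sentence(rng: np.random.Generator) -> str:
    if rng.random() < 0.04:
        return str(rng.choice(_SINGLE))
    tmpl, slots = _TEMPLATES[rng.integers(len(_TEMPLATES))]
    fills = [str(rng.choice(opts)) for opts in slots]
    s = tmpl.format(*fills)
    pre = _PREFIX[rng.integers(len(_PREFIX))] if rng.random() < 0.25 else ""
    return f"{pre} {s}".strip() if pre else s


def generate_sentences(n: int, seed: int, exclude: Sequence[str] = ()) -> List[str]:
    """Sample ``n`` distinct sentences, disjoint from ``exclude``."""
    rng = np.random.default_rng(seed)
    seen = set(s.upper() for s in exclude)
    out: List[str] = []
    tries = 0
    while len(out) < n:
        s = _sample_sentence(rng)
        if s not in seen:
            seen.add(s)
            out.append(s)
        tries += 1
        if tries > 200 * n + 10000:
            raise RuntimeError("grammar exhausted before reaching n distinct sentences")
    return out


def generate_corpus(n: int, seed: int) -> List[str]:
    """LM training text: sampled with repetition (natural n-gram frequencies)."""
    rng = np.random.default_rng(seed)
    return [_sample_sentence(rng) for _ in range(n)]


_PSEUDO_VOWELS = ["AA", "EH", "IY", "OW", "UW", "AE", "IH"]
_PSEUDO_CONS = ["B", "D", "F", "G", "K", "L", "M", "N", "P", "R", "S", "T", "V", "Z"]


def add_distractor_words(lexicon: Lexicon, n: int, seed: int,
                         confusable_frac: float = 0.5) -> List[str]:
    """Add ``n`` pseudo-words to the lexicon; returns the new words.

    A ``confusable_frac`` share are near-homophones of existing words (one
    phoneme substituted/deleted in a real pronunciation) — the vocabulary
    growth that actually hurts decoding; the rest are random CV-syllable
    strings.  Word strings are concatenated phoneme letters (``TAEKOW``),
    distinct from existing entries.
    """
    from .phonemes import ARPABET_39

    rng = np.random.default_rng(seed)
    base_prons = [lexicon.pronunciations(w)[0] for w in lexicon.words]
    existing_prons = {tuple(p) for w in lexicon.words
                      for p in lexicon.pronunciations(w)}
    added: List[str] = []
    while len(added) < n:
        if rng.random() < confusable_frac and base_prons:
            pron = list(base_prons[rng.integers(len(base_prons))])
            i = int(rng.integers(len(pron)))
            if len(pron) > 2 and rng.random() < 0.3:
                del pron[i]
            else:
                pron[i] = str(rng.choice(ARPABET_39))
        else:
            pron = []
            for _ in range(int(rng.integers(1, 4))):
                pron.append(str(rng.choice(_PSEUDO_CONS)))
                pron.append(str(rng.choice(_PSEUDO_VOWELS)))
        word = "".join(pron)
        if word in lexicon or word in added or tuple(pron) in existing_prons:
            continue
        lexicon.add(word, pron)
        added.append(word)
    return added


def distractor_corpus(words: Sequence[str], n_sentences: int, seed: int) -> List[str]:
    """Random sentences over distractor words, for LM count coverage."""
    rng = np.random.default_rng(seed)
    words = list(words)
    return [
        " ".join(str(rng.choice(words)) for _ in range(int(rng.integers(2, 7))))
        for _ in range(n_sentences)
    ]
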