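"""Phoneme inventory and pronouncing-lexicon handling.

The decoder operates over the 39 stress-stripped ARPABET phonemes plus two
special tokens: an interword silence token ``<sil>`` (which the decoder is
trained to emit at the end of every word) and the CTC blank.  Sentences are
converted to training label sequences by concatenating each word's first
pronunciation followed by ``<sil>``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

#: The 39 ARPABET phonemes of American English, stress digits stripped,
#: in fixed alphabetical order.  Index layout: phonemes 0..38, SIL 39, blank 40.
ARPABET_39: Tuple[str, ...] = (
    "AA", "AE", "AH", "AO", "AW", "AY", "B", "CH", "D", "DH",
    "EH", "ER", "EY", "F", "G", "HH", "IH", "IY", "JH", "K",
    "L", "M", "N", "NG", "OW", "OY", "P", "R", "S", "SH",
    "T", "TH", "UH", "UW", "V", "W", "Y", "Z", "ZH",
)

SIL = "<sil>"
BLANK = "<blank>"

_STRESS_RE = re.compile(r"^([A-Z]+)([0-2])$")
_ALT_RE = re.compile(r"^(.+)\((\d+)\)$")


class LexiconError(ValueError):
    """Raised for malformed lexicon files or out-of-inventory symbols."""


class OOVError(KeyError):
    """Raised when a sentence contains words absent from the lexicon."""

    def __init__(self, words: Sequence[str]):
        self.words = list(words)
        super().__init__(f"out-of-vocabulary word(s): {', '.join(self.words)}")


@dataclass(frozen=True)
class PhonemeInventory:
    """Fixed ordering of 39 phonemes + SIL + CTC blank (41 tokens)."""

    phonemes: Tuple[str, ...] = ARPABET_39
    sil_token: str = SIL
    blank_token: str = BLANK

    def __post_init__(self):
        if len(set(self.phonemes)) != len(self.phonemes):
            raise ValueError("duplicate phonemes in inventory")
        object.__setattr__(
            self, "_index",
            {p: i for i, p in enumerate(self.phonemes)}
            | {self.sil_token: len(self.phonemes),
               self.blank_token: len(self.phonemes) + 1},
        )

    @property
    def n_tokens(self) -> int:
        return len(self.phonemes) + 2

    @property
    def sil_index(self) -> int:
        return len(self.phonemes)

    @property
    def blank_index(self) -> int:
        return len(self.phonemes) + 1

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} not in inventory") from None

    def symbol(self, index: int) -> str:
        if 0 <= index < len(self.phonemes):
            return self.phonemes[index]
        if index == self.sil_index:
            return self.sil_token
        if index == self.blank_index:
            return self.blank_token
        raise IndexError(f"token index {index} out of range 0..{self.n_tokens - 1}")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def to_json(self) -> str:
        return json.dumps({"phonemes": list(self.phonemes),
                           "sil_token": self.sil_token,
                           "blank_token": self.blank_token})

    @classmethod
    def from_json(cls, s: str) -> "PhonemeInventory":
        d = json.loads(s)
        return cls(tuple(d["phonemes"]), d["sil_token"], d["blank_token"])


@dataclass
class Lexicon:
    """Word -> pronunciations (each a list of inventory phoneme symbols).

    The first-listed pronunciation is used for training targets; alternates
    are retained for the decoding lexicon.
    """

    inventory: PhonemeInventory
    entries: Dict[str, List[List[str]]] = field(default_factory=dict)

    def add(self, word: str, pron: Sequence[str]) -> None:
        if not pron:
            raise LexiconError(f"empty pronunciation for {word!r}")
        for p in pron:
            if p not in self.inventory or p in (self.inventory.sil_token,
                                                self.inventory.blank_token):
                raise LexiconError(f"symbol {p!r} (word {word!r}) not a phoneme")
        self.entries.setdefault(word.upper(), []).append(list(pron))

    def pronunciations(self, word: str) -> List[List[str]]:
        try:
            return self.entries[word.upper()]
        except KeyError:
            raise OOVError([word]) from None

    def __contains__(self, word: str) -> bool:
        return word.upper() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def words(self) -> List[str]:
        return sorted(self.entries)


def strip_stress(symbol: str) -> str:
    m = _STRESS_RE.match(symbol)
    return m.group(1) if m else symbol


def load_lexicon(path, inventory: PhonemeInventory | None = None) -> Lexicon:
    """Parse a CMUdict-format text lexicon.

    Lines are ``WORD  PH1 PH2 ...``; alternates are marked ``WORD(2)``;
    vowels may carry stress digits 0-2 (stripped); ``;;;`` lines are comments.
    """
    inventory = inventory or PhonemeInventory()
    lex = Lexicon(inventory)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(";;;"):
                continue
            parts = line.split()
            word = parts[0]
            m = _ALT_RE.match(word)
            if m:
                word = m.group(1)
            pron = [strip_stress(p) for p in parts[1:]]
            try:
                lex.add(word, pron)
            except LexiconError as e:
                raise LexiconError(f"{path}:{lineno}: {e}") from None
    return lex


_TOKEN_RE = re.compile(r"[A-Za-z']+")


def tokenize(sentence: str) -> List[str]:
    """Uppercase word tokens; punctuation stripped except intra-word apostrophes."""
    return [t.strip("'").upper() for t in _TOKEN_RE.findall(sentence) if t.strip("'")]


def sentence_to_labels(sentence: str, lexicon: Lexicon) -> List[int]:
    """Convert a sentence to phoneme indices with a SIL token after every word.

    Uses each word's first-listed pronunciation.  Raises :class:`OOVError`
    listing every out-of-vocabulary word; never falls back silently.
    """
    words = tokenize(sentence)
    oov = [w for w in words if w not in lexicon]
    if oov:
        raise OOVError(oov)
    inv = lexicon.inventory
    labels: List[int] = []
    for w in words:
        labels.extend(inv.index(p) for p in lexicon.pronunciations(w)[0])
        labels.append(inv.sil_index)
    return labels


def labels_to_symbols(labels: Sequence[int], inventory: PhonemeInventory) -> List[str]:
    return [inventory.symbol(i) for i in labels]
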