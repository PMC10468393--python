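"""Articulatory feature vectors for ARPABET phonemes.

Each phoneme maps to a 15-dimensional feature vector:

* consonant place, slots 0-6 (bilabial, labiodental, dental, alveolar,
  postalveolar, velar/palatal, glottal) — one-hot, except W which carries
  weight on both the bilabial and velar slots (it has aspects of both);
* consonant manner, slots 7-10 (nasal, plosive, fricative, approximant) —
  affricates CH/JH activate plosive and fricative together;
* voicing bit, slot 11;
* vowel coordinates, slots 12-14: tongue height in [0, 1] (low→high),
  backness in [0, 1] (front→back), lip-rounding bit.  Consonant slots are
  zero for vowels and vice versa.  SIL maps to the zero vector.

These vectors serve two roles: they drive the simulator's phoneme tuning,
and they are the articulatory reference against which neural similarity
structure is compared.  A CSV schema (header ``phoneme,<feature>...``)
accepts externally derived articulatory summary vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .phonemes import ARPABET_39, SIL, PhonemeInventory

FEATURE_NAMES: Tuple[str, ...] = (
    "bilabial", "labiodental", "dental", "alveolar", "postalveolar",
    "velar", "glottal",
    "nasal", "plosive", "fricative", "approximant",
    "voiced",
    "height", "backness", "rounding",
)

# place, manner(s), voiced
_CONSONANTS: Dict[str, tuple] = {
    "B":  (("bilabial",), ("plosive",), 1),
    "CH": (("postalveolar",), ("plosive", "fricative"), 0),
    "D":  (("alveolar",), ("plosive",), 1),
    "DH": (("dental",), ("fricative",), 1),
    "F":  (("labiodental",), ("fricative",), 0),
    "G":  (("velar",), ("plosive",), 1),
    "HH": (("glottal",), ("fricative",), 0),
    "JH": (("postalveolar",), ("plosive", "fricative"), 1),
    "K":  (("velar",), ("plosive",), 0),
    "L":  (("alveolar",), ("approximant",), 1),
    "M":  (("bilabial",), ("nasal",), 1),
    "N":  (("alveolar",), ("nasal",), 1),
    "NG": (("velar",), ("nasal",), 1),
    "P":  (("bilabial",), ("plosive",), 0),
    "R":  (("alveolar",), ("approximant",), 1),
    "S":  (("alveolar",), ("fricative",), 0),
    "SH": (("postalveolar",), ("fricative",), 0),
    "T":  (("alveolar",), ("plosive",), 0),
    "TH": (("dental",), ("fricative",), 0),
    "V":  (("labiodental",), ("fricative",), 1),
    "W":  (("bilabial", "velar"), ("approximant",), 1),
    "Y":  (("velar",), ("approximant",), 1),
    "Z":  (("alveolar",), ("fricative",), 1),
    "ZH": (("postalveolar",), ("fricative",), 1),
}

# height (low 0 .. high 1), backness (front 0 .. back 1), rounding
_VOWELS: Dict[str, tuple] = {
    "AA": (0.00, 1.00, 0),
    "AE": (0.10, 0.00, 0),
    "AH": (0.50, 0.50, 0),
    "AO": (0.25, 1.00, 1),
    "AW": (0.10, 0.60, 0),
    "AY": (0.10, 0.40, 0),
    "EH": (0.40, 0.10, 0),
    "ER": (0.50, 0.55, 0),
    "EY": (0.65, 0.10, 0),
    "IH": (0.80, 0.15, 0),
    "IY": (1.00, 0.00, 0),
    "OW": (0.60, 0.90, 1),
    "OY": (0.45, 0.80, 1),
    "UH": (0.80, 0.85, 1),
    "UW": (1.00, 1.00, 1),
}

#: consonants grouped by place of articulation (front of mouth to back) —
#: the ordering under which the similarity matrix shows block structure
PLACE_ORDER: Tuple[str, ...] = (
    "P", "B", "M", "W",          # bilabial
    "F", "V",                    # labiodental
    "TH", "DH",                  # dental
    "T", "D", "S", "Z", "N", "L", "R",   # alveolar
    "CH", "JH", "SH", "ZH",      # postalveolar
    "K", "G", "NG", "Y",         # velar/palatal
    "HH",                        # glottal
)

VOWELS: Tuple[str, ...] = tuple(sorted(_VOWELS))
CONSONANTS: Tuple[str, ...] = tuple(sorted(_CONSONANTS))


def _build_default() -> Dict[str, np.ndarray]:
    idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
    table: Dict[str, np.ndarray] = {}
    for ph, (places, manners, voiced) in _CONSONANTS.items():
        v = np.zeros(len(FEATURE_NAMES))
        w = 1.0 / len(places)
        for p in places:
            v[idx[p]] = w
        for m in manners:
            v[idx[m]] = 1.0
        v[idx["voiced"]] = voiced
        table[ph] = v
    for ph, (h, b, r) in _VOWELS.items():
        v = np.zeros(len(FEATURE_NAMES))
        v[idx["voiced"]] = 1.0
        v[idx["height"]], v[idx["backness"]], v[idx["rounding"]] = h, b, r
        table[ph] = v
    table[SIL] = np.zeros(len(FEATURE_NAMES))
    return table


@dataclass
class ArticulatoryFeatureTable:
    """phoneme -> articulatory feature vector; SIL -> zero vector."""

    feature_names: Tuple[str, ...] = FEATURE_NAMES
    vectors: Dict[str, np.ndarray] = field(default_factory=_build_default)

    def __post_init__(self):
        d = len(self.feature_names)
        for ph, v in self.vectors.items():
            if v.shape != (d,):
                raise ValueError(f"{ph}: vector length {v.shape} != {d}")

    @property
    def dim(self) -> int:
        return len(self.feature_names)

    def vector(self, phoneme: str) -> np.ndarray:
        return self.vectors[phoneme]

    def matrix(self, phonemes: Sequence[str]) -> np.ndarray:
        """Rows stacked in the given phoneme order."""
        return np.stack([self.vectors[p] for p in phonemes])

    def validate(self, inventory: PhonemeInventory) -> None:
        missing = [p for p in inventory.phonemes if p not in self.vectors]
        if missing:
            raise ValueError(f"feature table missing phonemes: {missing}")
        if not np.allclose(self.vectors[inventory.sil_token], 0):
            raise ValueError("SIL must map to the zero vector")

    def vowel_coords(self, vowels: Sequence[str] | None = None) -> np.ndarray:
        """(n_vowels, 2) array of (height, backness)."""
        vowels = list(vowels) if vowels is not None else list(VOWELS)
        hi = self.feature_names.index("height")
        bi = self.feature_names.index("backness")
        return np.stack([[self.vectors[v][hi], self.vectors[v][bi]]
                         for v in vowels])

    def vowel_formant_coords(self, vowels: Sequence[str] | None = None
                             ) -> np.ndarray:
        """Acoustic-style (F1-like, F2-like) coordinates per vowel.

        F1 falls with tongue height; F2 falls with backness and with lip
        rounding (which is why front/back is usually read off F2).  Both
        axes are returned on a 0-1 scale, larger = higher formant.
        """
        vowels = list(vowels) if vowels is not None else list(VOWELS)
        names = self.feature_names
        hi, bi, ri = (names.index("height"), names.index("backness"),
                      names.index("rounding"))
        out = np.empty((len(vowels), 2))
        for k, v in enumerate(vowels):
            h, b, r = (self.vectors[v][hi], self.vectors[v][bi],
                       self.vectors[v][ri])
            out[k, 0] = 1.0 - h
            out[k, 1] = 1.0 - (0.7 * b + 0.3 * r)
        return out

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {ph: vec for ph, vec in sorted(self.vectors.items())},
            index=list(self.feature_names),
        ).T
        df.index.name = "phoneme"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ArticulatoryFeatureTable":
        df = pd.read_csv(path, index_col="phoneme")
        names = tuple(df.columns)
        vecs = {ph: row.to_numpy(dtype=float) for ph, row in df.iterrows()}
        return cls(feature_names=names, vectors=vecs)

    @classmethod
    def default(cls) -> "ArticulatoryFeatureTable":
        return cls()


def place_ordered_consonants() -> List[str]:
    return list(PLACE_ORDER)
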