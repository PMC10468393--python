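import numpy as np
import pytest

from speechbci.articulation import ArticulatoryFeatureTable
from speechbci.corpus import default_lexicon
from speechbci.phonemes import Lexicon, PhonemeInventory


@pytest.fixture(scope="session")
def inv():
    return PhonemeInventory()


@pytest.fixture(scope="session")
def table():
    return ArticulatoryFeatureTable.default()


@pytest.fixture(scope="session")
def lexicon50(inv):
    return default_lexicon(inv)


@pytest.fixture()
def toy_lexicon(inv):
    lex = Lexicon(inv)
    lex.add("CAT", ["K", "AE", "T"])
    lex.add("BAT", ["B", "AE", "T"])
    lex.add("BAD", ["B", "AE", "D"])
    lex.add("AT", ["AE", "T"])
    lex.add("A", ["AH"])
    lex.add("THE", ["DH", "AH"])
    return lex
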