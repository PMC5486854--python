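import numpy as np
import pandas as pd
import pytest

from phonovalence import (
    LANGUAGES,
    ValenceLexicon,
    build_schema,
    get_inventory,
)


@pytest.fixture(scope="session", params=LANGUAGES)
def language(request):
    return request.param


@pytest.fixture(scope="session")
def nl_inventory():
    return get_inventory("nl")


@pytest.fixture(scope="session")
def en_inventory():
    return get_inventory("en")


def make_lexicon(words, language="nl", valences=None):
    """Build a small lexicon from whitespace-dialect (or Pinyin) strings."""
    valences = valences if valences is not None else [5.0] * len(words)
    return ValenceLexicon(pd.DataFrame({
        "word": [w.replace(" ", "") for w in words],
        "language": language,
        "transcription": words,
        "valence": valences,
    }))


def random_transcription_string(rng, inventory, min_len=1, max_len=10):
    """A random symbol string with at least one vowel (whitespace dialect)."""
    symbols = [p.symbol for p in inventory.phonemes]
    vowels = [p.symbol for p in inventory.vowels]
    n = int(rng.integers(min_len, max_len + 1))
    toks = [symbols[rng.integers(len(symbols))] for _ in range(n)]
    if not any(t in vowels for t in toks):
        toks[rng.integers(len(toks))] = vowels[rng.integers(len(vowels))]
    return " ".join(toks)
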