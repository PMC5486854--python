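"""Phoneme inventories, transcription parsing and syllabification.

This module is the phonological substrate for the feature schema: it knows
what a phoneme is (a segmental symbol annotated with articulatory classes),
how to read a word's transcription, and how to cut a phoneme string into
syllables.

Two transcription dialects are supported:

* a neutral **whitespace dialect** in which a word is a space-separated
  sequence of inventory symbols (``"p l a n t"``), used for English, Dutch
  and German; and
* a strict **numeric-tone Pinyin dialect** for Mandarin, in which each
  syllable is an initial+final romanisation followed by a mandatory tone
  digit 1-5 (``"bei1 shang1"``, 5 = neutral tone).

Inventories are compact research inventories (roughly 40 symbols per
language) shipped as editable TSV files, not exhaustive phonologies; the
feature schema only needs articulatory class memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "Phoneme",
    "PhonemeInventory",
    "Transcription",
    "Syllable",
    "LANGUAGES",
    "get_inventory",
    "parse_transcription",
    "parse_pinyin",
    "render_transcription",
    "syllabify",
]

LANGUAGES = ("en", "nl", "de", "zh")

MANNERS = frozenset(
    {"nasal", "plosive", "fricative", "affricate", "approximant", "lateral", "trill", "none"}
)
PLACES = frozenset(
    {"bilabial", "labiodental", "dental", "alveolar", "postalveolar",
     "palatal", "velar", "uvular", "glottal", "none"}
)
HEIGHTS = frozenset(
    {"close", "near-close", "close-mid", "mid", "open-mid", "near-open", "open", "none"}
)
BACKNESSES = frozenset({"front", "near-front", "central", "near-back", "back", "none"})


@dataclass(frozen=True)
class Phoneme:
    """A segmental symbol annotated with articulatory feature classes.

    Consonants carry ``manner``/``place`` and have ``height = "none"``;
    vowels carry ``height``/``backness`` and have ``manner = "none"``.
    """

    symbol: str
    sound_class: str  # "consonant" | "vowel"
    manner: str = "none"
    place: str = "none"
    voiced: bool = False
    height: str = "none"
    backness: str = "none"
    rounded: bool = False
    long: bool = False
    diphthong: bool = False

    def __post_init__(self) -> None:
        if self.sound_class not in ("consonant", "vowel"):
            raise ValueError(f"bad sound_class {self.sound_class!r} for {self.symbol!r}")
        if self.manner not in MANNERS:
            raise ValueError(f"bad manner {self.manner!r} for {self.symbol!r}")
        if self.place not in PLACES:
            raise ValueError(f"bad place {self.place!r} for {self.symbol!r}")
        if self.height not in HEIGHTS:
            raise ValueError(f"bad height {self.height!r} for {self.symbol!r}")
        if self.backness not in BACKNESSES:
            raise ValueError(f"bad backness {self.backness!r} for {self.symbol!r}")
        if self.sound_class == "consonant" and (self.manner == "none" or self.height != "none"):
            raise ValueError(f"consonant {self.symbol!r} must have a manner and no height")
        if self.sound_class == "vowel" and (self.height == "none" or self.manner != "none"):
            raise ValueError(f"vowel {self.symbol!r} must have a height and no manner")

    @property
    def is_vowel(self) -> bool:
        return self.sound_class == "vowel"

    @property
    def is_consonant(self) -> bool:
        return self.sound_class == "consonant"


@dataclass(frozen=True)
class PhonemeInventory:
    """The phoneme set of one language plus its legal syllable onsets."""

    language: str
    phonemes: tuple[Phoneme, ...]
    legal_onsets: frozenset[tuple[str, ...]] = frozenset()
    symbol_map: dict[str, Phoneme] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.language not in LANGUAGES:
            raise ValueError(f"unknown language {self.language!r}; expected one of {LANGUAGES}")
        symbols = [p.symbol for p in self.phonemes]
        dup = {s for s in symbols if symbols.count(s) > 1}
        if dup:
            raise ValueError(f"duplicate symbols in {self.language} inventory: {sorted(dup)}")
        object.__setattr__(self, "symbol_map", {p.symbol: p for p in self.phonemes})

    def lookup(self, symbol: str) -> Phoneme:
        """Look up one transcription symbol; unmapped symbols are an error."""
        try:
            return self.symbol_map[symbol]
        except KeyError:
            raise KeyError(
                f"symbol {symbol!r} is not in the {self.language} inventory"
            ) from None

    @property
    def vowels(self) -> tuple[Phoneme, ...]:
        return tuple(p for p in self.phonemes if p.is_vowel)

    @property
    def consonants(self) -> tuple[Phoneme, ...]:
        return tuple(p for p in self.phonemes if p.is_consonant)


@dataclass(frozen=True)
class Transcription:
    """An ordered phoneme sequence with optional syllable boundaries and tones.

    ``syllable_boundaries`` holds the start index of every syllable after the
    first, strictly increasing and strictly inside the sequence.  ``tones``
    (Mandarin only) holds one tone digit 1-5 per syllable.
    """

    language: str
    phonemes: tuple[Phoneme, ...]
    syllable_boundaries: tuple[int, ...] = ()
    tones: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.phonemes)
        bounds = self.syllable_boundaries
        if any(not (0 < b < n) for b in bounds):
            raise ValueError(f"syllable boundaries {bounds} out of range for {n} phonemes")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"syllable boundaries {bounds} not strictly increasing")
        if self.tones:
            if self.language != "zh":
                raise ValueError("tones are only valid for zh transcriptions")
            if any(t not in range(1, 6) for t in self.tones):
                raise ValueError(f"tones must be in 1..5, got {self.tones}")
            if len(self.tones) != len(bounds) + 1:
                raise ValueError(
                    f"{len(self.tones)} tones for {len(bounds) + 1} syllables"
                )

    def __len__(self) -> int:
        return len(self.phonemes)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(p.symbol for p in self.phonemes)


@dataclass(frozen=True)
class Syllable:
    """Onset consonants, vowel nucleus and coda consonants of one syllable."""

    onset: tuple[Phoneme, ...]
    nucleus: tuple[Phoneme, ...]
    coda: tuple[Phoneme, ...]

    def __post_init__(self) -> None:
        if not self.nucleus:
            raise ValueError("syllable nucleus may not be empty")
        if any(p.is_vowel for p in self.onset) or any(p.is_vowel for p in self.coda):
            raise ValueError("onset and coda must be consonantal")
        if any(p.is_consonant for p in self.nucleus):
            raise ValueError("nucleus must be vocalic")

    @property
    def phonemes(self) -> tuple[Phoneme, ...]:
        return self.onset + self.nucleus + self.coda


# ---------------------------------------------------------------------------
# bundled data


def _data_text(*parts: str) -> str:
    ref = resources.files("phonovalence").joinpath("data", *parts)
    return ref.read_text(encoding="utf-8")


def _parse_bool(s: str) -> bool:
    if s not in ("true", "false"):
        raise ValueError(f"expected true/false, got {s!r}")
    return s == "true"


@lru_cache(maxsize=None)
def get_inventory(language: str) -> PhonemeInventory:
    """Load the bundled inventory (and legal-onset list) for one language."""
    if language not in LANGUAGES:
        raise ValueError(f"unknown language {language!r}; expected one of {LANGUAGES}")
    lines = _data_text("inventories", f"{language}.tsv").splitlines()
    header = lines[0].split("\t")
    phonemes = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        phonemes.append(
            Phoneme(
                symbol=row["symbol"],
                sound_class=row["sound_class"],
                manner=row["manner"],
                place=row["place"],
                voiced=_parse_bool(row["voiced"]),
                height=row["height"],
                backness=row["backness"],
                rounded=_parse_bool(row["rounded"]),
                long=_parse_bool(row["long"]),
                diphthong=_parse_bool(row["diphthong"]),
            )
        )
    onsets = set()
    for line in _data_text("onsets", f"{language}.txt").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        onsets.add(tuple(line.split()))
    inv = PhonemeInventory(language, tuple(phonemes), frozenset(onsets))
    for onset in inv.legal_onsets:
        for sym in onset:
            if not inv.lookup(sym).is_consonant:
                raise ValueError(f"onset {onset} contains non-consonant {sym!r}")
    return inv


# ---------------------------------------------------------------------------
# parsing


def parse_transcription(text: str, inventory: PhonemeInventory) -> Transcription:
    """Parse a whitespace-separated symbol string against an inventory.

    Every token must be a symbol of the inventory; an unmapped token is an
    error naming the token and its (1-based) position, never a silent skip.
    Syllabification is deferred to :func:`syllabify`.
    """
    tokens = text.split()
    if not tokens:
        raise ValueError("empty transcription")
    phonemes = []
    for i, tok in enumerate(tokens, start=1):
        try:
            phonemes.append(inventory.lookup(tok))
        except KeyError:
            raise ValueError(
                f"unknown symbol {tok!r} at token {i} of {text!r} "
                f"({inventory.language} inventory)"
            ) from None
    return Transcription(inventory.language, tuple(phonemes))


@lru_cache(maxsize=None)
def _pinyin_tables() -> tuple[dict[str, tuple[str, ...]], dict[str, tuple[str, ...]]]:
    def load(name: str, key: str) -> dict[str, tuple[str, ...]]:
        table = {}
        lines = _data_text(name).splitlines()
        header = lines[0].split("\t")
        assert header == [key, "phonemes"]
        for line in lines[1:]:
            if not line.strip():
                continue
            k, syms = line.split("\t")
            table[k] = tuple(syms.split())
        return table

    return load("pinyin_initials.tsv", "initial"), load("pinyin_finals.tsv", "final")


@lru_cache(maxsize=1)
def _initials_by_length() -> tuple[str, ...]:
    initials, _ = _pinyin_tables()
    return tuple(sorted(initials, key=len, reverse=True))


def parse_pinyin(text: str) -> Transcription:
    """Parse numeric-tone Pinyin into a Mandarin transcription.

    Each whitespace-separated syllable must be ``[initial]final`` plus a
    trailing tone digit 1-5 (5 = neutral tone); tone diacritics are rejected.
    Syllable boundaries follow the Pinyin syllables verbatim.
    """
    inv = get_inventory("zh")
    initials, finals = _pinyin_tables()
    chunks = text.split()
    if not chunks:
        raise ValueError("empty Pinyin transcription")
    phonemes: list[Phoneme] = []
    boundaries: list[int] = []
    tones: list[int] = []
    for chunk in chunks:
        body, tone_char = chunk[:-1], chunk[-1:]
        if not tone_char.isdigit():
            raise ValueError(f"Pinyin syllable {chunk!r} lacks a trailing tone digit")
        tone = int(tone_char)
        if tone not in range(1, 6):
            raise ValueError(f"tone {tone} out of range 1-5 in syllable {chunk!r}")
        # longest-match initial, then the remainder must be a known final
        initial = ""
        for cand in _initials_by_length():
            if body.startswith(cand) and body[len(cand):] in finals:
                initial = cand
                break
        final = body[len(initial):]
        if final not in finals:
            raise ValueError(f"unparseable Pinyin syllable {chunk!r}")
        if phonemes:
            boundaries.append(len(phonemes))
        for sym in (initials[initial] if initial else ()) + finals[final]:
            phonemes.append(inv.lookup(sym))
        tones.append(tone)
    return Transcription("zh", tuple(phonemes), tuple(boundaries), tuple(tones))


def render_transcription(t: Transcription) -> str:
    """Render a transcription back to the whitespace symbol dialect."""
    return " ".join(t.symbols)


# ---------------------------------------------------------------------------
# syllabification


def _split_syllable(phonemes: Sequence[Phoneme]) -> Syllable:
    i = 0
    while i < len(phonemes) and phonemes[i].is_consonant:
        i += 1
    j = i
    while j < len(phonemes) and phonemes[j].is_vowel:
        j += 1
    if i == j:
        raise ValueError("syllable without a vowel nucleus")
    if any(p.is_vowel for p in phonemes[j:]):
        raise ValueError("syllable has a second vowel cluster; bad boundary")
    return Syllable(tuple(phonemes[:i]), tuple(phonemes[i:j]), tuple(phonemes[j:]))


def syllabify(t: Transcription, inventory: PhonemeInventory | None = None) -> tuple[Syllable, ...]:
    """Cut a transcription into syllables.

    If the transcription already carries syllable boundaries (the Pinyin
    path) they are respected verbatim.  Otherwise segmentation follows the
    maximal-onset principle: each intervocalic consonant cluster donates its
    longest suffix that is a legal onset of the language to the following
    syllable and keeps the rest as coda.  Word-initial consonants always
    form the first onset and word-final consonants the last coda.
    """
    if inventory is None:
        inventory = get_inventory(t.language)
    if inventory.language != t.language:
        raise ValueError(
            f"inventory language {inventory.language!r} != transcription language {t.language!r}"
        )
    if not any(p.is_vowel for p in t.phonemes):
        raise ValueError("cannot syllabify a vowel-free transcription")

    if t.syllable_boundaries:
        cuts = (0,) + t.syllable_boundaries + (len(t.phonemes),)
        return tuple(_split_syllable(t.phonemes[a:b]) for a, b in zip(cuts, cuts[1:]))

    # nuclei = maximal runs of vowels
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(t.phonemes)
    while i < n:
        if t.phonemes[i].is_vowel:
            j = i
            while j < n and t.phonemes[j].is_vowel:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1

    syllables = []
    onset_start = 0
    for k, (a, b) in enumerate(runs):
        onset = t.phonemes[onset_start:a]
        if k + 1 < len(runs):
            cluster = t.phonemes[b:runs[k + 1][0]]
            # longest legal-onset suffix of the cluster opens the next syllable
            split = len(cluster)
            for cut in range(len(cluster) + 1):
                if tuple(p.symbol for p in cluster[cut:]) in inventory.legal_onsets or cut == len(cluster):
                    split = cut
                    break
            coda = cluster[:split]
            onset_start = b + split
        else:
            coda = t.phonemes[b:]
        syllables.append(Syllable(tuple(onset), tuple(t.phonemes[a:b]), tuple(coda)))
    return tuple(syllables)


def transcription_with_boundaries(t: Transcription,
                                  inventory: PhonemeInventory | None = None) -> Transcription:
    """Return ``t`` with syllable boundaries filled in (no-op if present)."""
    if t.syllable_boundaries or len(t.phonemes) == 0:
        return t
    sylls = syllabify(t, inventory)
    bounds = []
    pos = 0
    for s in sylls[:-1]:
        pos += len(s.phonemes)
        bounds.append(pos)
    return Transcription(t.language, t.phonemes, tuple(bounds), t.tones)
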