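"""Phonological feature schema and per-word feature vectors.

The master feature list (105 named features, bundled as
``data/feature_specs.tsv``) spans five families:

1. ``word_count`` — how many phonemes of a class the word contains
   (e.g. the number of nasals in the word);
2. ``word_proportion`` — that count divided by the word's phoneme count;
3. ``onset`` — the count restricted to the first syllable;
4. ``first_consonant`` — an indicator for the word-initial phoneme's class
   (0 for vowel-initial words);
5. ``vowel`` — indicator banks describing the first vowel (height,
   backness, rounding, length, diphthong) and, for Mandarin, the tone of
   the first syllable plus a mean-tone level.

Each language sees only the subset of the master list whose classes occur
in that language: dentals are English-only, trills and uvulars
Dutch/German-only, tone Mandarin-only, and the close-mid / open-mid /
near-front / near-back vowel distinctions are absent from Mandarin.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .phonology import (
    LANGUAGES,
    Phoneme,
    Transcription,
    _data_text,
    get_inventory,
    syllabify,
)

__all__ = [
    "FeatureSpec",
    "FeatureSchema",
    "FeatureVector",
    "master_specs",
    "build_schema",
    "extract_features",
    "nasal_first",
    "FeatureExtractor",
]

FAMILIES = ("word_count", "word_proportion", "onset", "first_consonant", "vowel")
STATISTICS = ("count", "proportion", "indicator", "level")


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature: a phoneme-class predicate plus a statistic."""

    name: str
    family: str
    predicate: str
    statistic: str
    languages: frozenset[str]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"bad family {self.family!r} for {self.name}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"bad statistic {self.statistic!r} for {self.name}")
        if self.family == "word_proportion" and self.statistic != "proportion":
            raise ValueError(f"{self.name}: word_proportion features must be proportions")
        if self.family == "first_consonant" and self.statistic != "indicator":
            raise ValueError(f"{self.name}: first_consonant features must be indicators")

    def matches(self, p: Phoneme) -> bool:
        """Does this spec's phoneme-class predicate hold for ``p``?"""
        return _predicate_matches(self.predicate, p)


def _predicate_matches(predicate: str, p: Phoneme) -> bool:
    if predicate == "any":
        return True
    if predicate == "voiced_consonant":
        return p.is_consonant and p.voiced
    if predicate == "vowel_long":
        return p.is_vowel and p.long
    if predicate == "vowel_diphthong":
        return p.is_vowel and p.diphthong
    if predicate == "vowel_rounded":
        return p.is_vowel and p.rounded
    attr, _, value = predicate.partition("=")
    if not value:
        raise ValueError(f"phoneme predicate expected, got {predicate!r}")
    return getattr(p, attr) == value


@dataclass(frozen=True)
class FeatureSchema:
    """The ordered feature list of one language; vector positions are stable."""

    language: str
    specs: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        bad = [s.name for s in self.specs if self.language not in s.languages]
        if bad:
            raise ValueError(f"specs not defined for {self.language}: {bad}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class FeatureVector:
    """One word's numeric values, aligned to a schema's feature order."""

    word_id: str
    values: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@lru_cache(maxsize=1)
def master_specs() -> tuple[FeatureSpec, ...]:
    """The bundled master list of 105 named feature specs."""
    lines = _data_text("feature_specs.tsv").splitlines()
    assert lines[0].split("\t") == ["name", "family", "predicate", "statistic", "languages"]
    specs = []
    for line in lines[1:]:
        if not line.strip():
            continue
        name, family, predicate, statistic, languages = line.split("\t")
        specs.append(
            FeatureSpec(name, family, predicate, statistic,
                        frozenset(languages.split(",")))
        )
    return tuple(specs)


@lru_cache(maxsize=None)
def build_schema(language: str) -> FeatureSchema:
    """The ordered feature schema for one language (subset of the master list)."""
    if language not in LANGUAGES:
        raise ValueError(f"unknown language {language!r}; expected one of {LANGUAGES}")
    specs = tuple(s for s in master_specs() if language in s.languages)
    return FeatureSchema(language, specs)


def nasal_first(t: Transcription) -> int:
    """1 iff the word-initial phoneme is a nasal consonant, else 0."""
    if len(t.phonemes) == 0:
        raise ValueError("empty transcription")
    p = t.phonemes[0]
    return int(p.is_consonant and p.manner == "nasal")


class FeatureExtractor:
    """Vectorised feature extraction for one schema.

    Per-symbol class memberships are precomputed once, so extracting a
    word costs one membership-matrix sum plus a handful of lookups.  Used
    heavily by the corpus pipeline; :func:`extract_features` is the
    single-word convenience wrapper.
    """

    def __init__(self, schema: FeatureSchema):
        self.schema = schema
        self.inventory = get_inventory(schema.language)

        # unique phoneme-class predicates used by the count-like families
        preds: list[str] = []
        for s in schema.specs:
            if s.family in ("word_count", "word_proportion", "onset", "first_consonant"):
                if s.predicate not in ("syllable",) and s.predicate not in preds:
                    preds.append(s.predicate)
        self._preds = preds
        self._pred_idx = {p: i for i, p in enumerate(preds)}
        self._membership = {
            ph.symbol: np.array([_predicate_matches(p, ph) for p in preds], dtype=float)
            for ph in self.inventory.phonemes
        }

    def __call__(self, t: Transcription, word_id: str = "") -> FeatureVector:
        if t.language != self.schema.language:
            raise ValueError(
                f"transcription language {t.language!r} does not match "
                f"schema language {self.schema.language!r}"
            )
        if len(t.phonemes) == 0:
            raise ValueError("empty transcription")
        sylls = syllabify(t, self.inventory)
        n = len(t.phonemes)

        M = np.stack([self._membership[p.symbol] for p in t.phonemes])
        word_counts = M.sum(axis=0)
        first_syll_counts = M[: len(sylls[0].phonemes)].sum(axis=0)
        first = t.phonemes[0]
        first_row = self._membership[first.symbol] if first.is_consonant else None
        first_vowel = next(p for p in t.phonemes if p.is_vowel)

        values = []
        for s in self.schema.specs:
            if s.family == "word_count":
                if s.predicate == "syllable":
                    values.append(float(len(sylls)))
                else:
                    values.append(word_counts[self._pred_idx[s.predicate]])
            elif s.family == "word_proportion":
                values.append(word_counts[self._pred_idx[s.predicate]] / n)
            elif s.family == "onset":
                values.append(first_syll_counts[self._pred_idx[s.predicate]])
            elif s.family == "first_consonant":
                if first_row is None:  # vowel-initial: all indicators 0
                    values.append(0.0)
                else:
                    values.append(first_row[self._pred_idx[s.predicate]])
            else:  # vowel family: first-vowel banks and tone
                if s.predicate == "tone_mean":
                    values.append(float(np.mean(t.tones)) if t.tones else 0.0)
                elif s.predicate.startswith("tone="):
                    level = int(s.predicate.split("=")[1])
                    values.append(float(bool(t.tones) and t.tones[0] == level))
                else:
                    values.append(float(_predicate_matches(s.predicate, first_vowel)))
        return FeatureVector(word_id, tuple(values))


def extract_features(t: Transcription, schema: FeatureSchema,
                     word_id: str = "") -> FeatureVector:
    """Compute one word's feature vector under a language schema.

    The transcription must have been parsed with the schema's language
    inventory; a language mismatch is an error.
    """
    return _cached_extractor(schema)(t, word_id)


@lru_cache(maxsize=8)
def _cached_extractor(schema: FeatureSchema) -> FeatureExtractor:
    return FeatureExtractor(schema)
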