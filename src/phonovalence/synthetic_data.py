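"""Synthetic lexicons and rating experiments with known ground truth.

Real valence norms and phonological transcriptions (ANEW-style ratings,
CELEX-style transcriptions) are licensed resources, so every analysis in
this package is exercised against generated stand-ins whose statistical
structure is controlled:

* :func:`generate_lexicon` samples phonotactically legal words from a
  language's inventory and assigns each a 1-9 valence rating
  ``mu + beta * nasal_first + Normal(0, sigma)`` (clipped to the scale).
  ``beta`` is the planted sound-symbolic effect the pipeline should
  recover: positive for Mandarin-like lexicons, negative for
  Germanic-like ones.

* :func:`generate_responses` simulates the two-alternative rating task:
  each trial is a Bernoulli draw whose log-odds combine a group baseline,
  the crossover interaction (``+gamma * nasal_first`` for Mandarin
  speakers, ``-gamma * nasal_first`` for Dutch speakers), and additive
  participant and item effects; trials go missing at a fixed rate and
  response times are lognormal.

Seeds are mandatory; there is no hidden global randomness, and the same
seed always reproduces the same table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .phonology import get_inventory
from .valence_pipeline import ValenceLexicon

__all__ = [
    "LexiconModel",
    "ResponseModel",
    "generate_lexicon",
    "generate_responses",
    "simulate_experiment",
]

# simple per-language coda repertoires for word sampling (generator-only;
# syllabification never depends on these)
_CODAS = {
    "en": ["", "", "n", "m", "N", "t", "d", "k", "s", "l", "n t", "n d", "s t"],
    "nl": ["", "", "n", "m", "N", "t", "k", "s", "l", "r", "n t", "s t"],
    "de": ["", "", "n", "m", "N", "t", "k", "s", "l", "r", "n t", "s t"],
}

# Pinyin finals usable without an initial (vowel-initial syllables); finals
# beginning in i/u/v require a glide initial in standard romanisation
_ZH_BARE_FINALS = ["a", "o", "e", "ai", "ei", "ao", "ou", "an", "en", "ang", "eng", "er"]
_ZH_FINALS = _ZH_BARE_FINALS + [
    "i", "u", "ong", "ia", "ie", "iao", "iu", "ian", "in", "iang", "ing",
    "ua", "uo", "uai", "ui", "uan", "un", "uang",
]
_ZH_NASAL_INITIALS = ["m", "n"]
_ZH_OTHER_INITIALS = ["b", "p", "f", "d", "t", "l", "g", "k", "h", "j", "q", "x",
                      "zh", "ch", "sh", "r", "z", "c", "s", "y", "w"]
# finals compatible with the palatal series vs. the rest (coarse but keeps
# generated syllables parseable and inventory-legal)
_ZH_PALATALS = {"j", "q", "x", "y"}
_ZH_PALATAL_FINALS = ["i", "ia", "ie", "iao", "iu", "ian", "in", "iang", "ing", "u", "ue"]


@dataclass(frozen=True)
class LexiconModel:
    """Parameters of a synthetic valence lexicon.

    Defaults emulate the shape of valence-norm lexicons: mostly two-syllable
    words (mean just above 2 syllables), a scale midpoint of 5, and a
    planted nasal-first effect ``nasal_first_effect`` on the 1-9 scale.
    """

    language: str
    n_words: int = 5000
    syllable_count_probs: tuple[float, ...] = (0.15, 0.60, 0.20, 0.05)  # 1..4 syllables
    nasal_first_rate: float = 0.25
    valence_mean: float = 5.0
    nasal_first_effect: float = 0.3
    valence_sd: float = 1.5
    log_frequency_mean: float = 14.0
    log_frequency_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nasal_first_rate < 1:
            raise ValueError("nasal_first_rate must be strictly inside (0, 1)")
        if self.valence_sd < 0:
            raise ValueError("valence_sd must be non-negative")
        if abs(sum(self.syllable_count_probs) - 1) > 1e-9:
            raise ValueError("syllable_count_probs must sum to 1")


def _sample_word_symbols(rng: np.random.Generator, inv, n_syll: int, nasal: bool,
                         nasal_onsets: list, other_onsets: list,
                         vowels: list, codas: list) -> list[str]:
    symbols: list[str] = []
    for k in range(n_syll):
        if k == 0:
            if nasal:
                onset = nasal_onsets[rng.integers(len(nasal_onsets))]
            else:
                # vowel-initial words are possible non-nasal words too
                if rng.random() < 0.1:
                    onset = ()
                else:
                    onset = other_onsets[rng.integers(len(other_onsets))]
        else:
            # non-initial syllables always take an onset so nuclei stay apart
            pool = nasal_onsets + other_onsets
            onset = pool[rng.integers(len(pool))]
        symbols.extend(onset)
        symbols.append(vowels[rng.integers(len(vowels))])
        if k == n_syll - 1:
            coda = codas[rng.integers(len(codas))]
            if coda:
                symbols.extend(coda.split())
        elif rng.random() < 0.2:
            symbols.append("n" if "n" in inv.symbol_map else "t")
    return symbols


def _sample_zh_syllable(rng: np.random.Generator, position: int, nasal: bool) -> str:
    tone = int(rng.integers(1, 6))
    if nasal:
        initial = _ZH_NASAL_INITIALS[rng.integers(2)]
    else:
        # onsetless syllables allowed word-initially for non-nasal words
        if position == 0 and rng.random() < 0.1:
            return _ZH_BARE_FINALS[rng.integers(len(_ZH_BARE_FINALS))] + str(tone)
        initial = _ZH_OTHER_INITIALS[rng.integers(len(_ZH_OTHER_INITIALS))]
    if initial in _ZH_PALATALS:
        final = _ZH_PALATAL_FINALS[rng.integers(len(_ZH_PALATAL_FINALS))]
    else:
        final = _ZH_FINALS[rng.integers(len(_ZH_FINALS))]
    return initial + final + str(tone)


def generate_lexicon(m: LexiconModel) -> ValenceLexicon:
    """Sample a synthetic valence lexicon under ``m`` (deterministic per seed)."""
    inv = get_inventory(m.language)
    rng = np.random.default_rng(m.seed)

    if m.language != "zh":
        onsets = sorted(inv.legal_onsets)
        nasal_onsets = [o for o in onsets
                        if inv.lookup(o[0]).manner == "nasal"]
        other_onsets = [o for o in onsets if o not in nasal_onsets]
        if not nasal_onsets:
            raise ValueError(
                f"{m.language} inventory has no nasal onsets but nasal_first_rate > 0"
            )
        vowels = [p.symbol for p in inv.vowels]
        codas = [c for c in _CODAS[m.language]
                 if all(s in inv.symbol_map for s in c.split())]

    n_syll = rng.choice(np.arange(1, 5), size=m.n_words, p=m.syllable_count_probs)
    nasal = rng.random(m.n_words) < m.nasal_first_rate
    valence = np.clip(
        m.valence_mean + m.nasal_first_effect * nasal
        + rng.normal(0.0, m.valence_sd, m.n_words),
        1.0, 9.0,
    )
    log_freq = rng.normal(m.log_frequency_mean, m.log_frequency_sd, m.n_words)

    words, transcriptions = [], []
    seen: dict[str, int] = {}
    for i in range(m.n_words):
        if m.language == "zh":
            sylls = [_sample_zh_syllable(rng, k, nasal[i] and k == 0)
                     for k in range(n_syll[i])]
            transcription = " ".join(sylls)
            word = "".join(sylls)
        else:
            symbols = _sample_word_symbols(rng, inv, int(n_syll[i]), bool(nasal[i]),
                                           nasal_onsets, other_onsets, vowels, codas)
            transcription = " ".join(symbols)
            word = "".join(symbols)
        k = seen.get(word, 0)
        seen[word] = k + 1
        if k:
            word = f"{word}-{k + 1}"
        words.append(word)
        transcriptions.append(transcription)

    data = pd.DataFrame({
        "word": words,
        "language": m.language,
        "transcription": transcriptions,
        "valence": np.round(valence, 6),
        "log_frequency": np.round(log_freq, 6),
        "nasal_first": nasal.astype(int),  # generator ground truth, not a feature
    })
    return ValenceLexicon(data)


@dataclass(frozen=True)
class ResponseModel:
    """Parameters of a simulated two-alternative rating experiment.

    ``gamma`` is the crossover interaction on the log-odds scale: positive
    gamma pushes Mandarin speakers toward rating nasal-first items positive
    and Dutch speakers toward rating them negative.  Defaults give roughly
    55-60% positive responses overall, sub-1% missingness and ~770 ms
    response times, the regime of a fast binary judgment task.
    """

    alpha_zh: float = 0.2
    alpha_nl: float = 0.2
    gamma: float = 1.4
    participant_sd: float = 0.5
    item_sd: float = 0.3
    miss_rate: float = 0.007
    item_dropout: float = 0.0  # chance an item is lost wholesale (all trials)
    rt_meanlog: float = 6.57   # lognormal location: median ~713 ms
    rt_sdlog: float = 0.35
    n_participants: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.miss_rate < 1:
            raise ValueError("miss_rate must lie in [0, 1)")
        if not 0 <= self.item_dropout < 1:
            raise ValueError("item_dropout must lie in [0, 1)")
        for name in ("participant_sd", "item_sd", "rt_sdlog"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


_GROUP_SIGN = {"zh": +1.0, "nl": -1.0}


def generate_responses(rm: ResponseModel, items: Sequence[tuple[str, int]],
                       group: str, seed: int,
                       item_language: str | None = None) -> pd.DataFrame:
    """Simulate one participant group rating a list of items.

    ``items`` is a sequence of (item_id, nasal_first) pairs; ``group`` is
    the raters' native language (zh or nl), which sets the sign of the
    nasal-first effect.  Responses are coded 2 = positive, 1 = negative;
    missed trials have empty response and rt.  Deterministic per seed.
    """
    if group not in _GROUP_SIGN:
        raise ValueError(f"group must be 'zh' or 'nl', got {group!r}")
    items = list(items)
    if not items:
        raise ValueError("items must be non-empty")
    rng = np.random.default_rng(seed)
    item_ids = np.array([i for i, _ in items])
    nasal = np.array([int(n) for _, n in items], dtype=float)
    alpha = rm.alpha_zh if group == "zh" else rm.alpha_nl

    n_p, n_i = rm.n_participants, len(items)
    p_eff = rng.normal(0.0, rm.participant_sd, n_p)
    i_eff = rng.normal(0.0, rm.item_sd, n_i)
    logits = alpha + _GROUP_SIGN[group] * rm.gamma * nasal[None, :] \
        + p_eff[:, None] + i_eff[None, :]
    prob = expit(logits)
    positive = rng.random((n_p, n_i)) < prob
    missing = rng.random((n_p, n_i)) < rm.miss_rate
    # wholesale item loss (e.g. a stimulus that never played): every trial
    # of a dropped item goes missing, leaving the design unbalanced
    if rm.item_dropout:
        missing |= (rng.random(n_i) < rm.item_dropout)[None, :]
    rt = rng.lognormal(rm.rt_meanlog, rm.rt_sdlog, (n_p, n_i))

    response = np.where(positive, 2.0, 1.0)
    response[missing] = np.nan
    rt[missing] = np.nan

    part_ids = np.array([f"{group}_p{k + 1:03d}" for k in range(n_p)])
    return pd.DataFrame({
        "participant_id": np.repeat(part_ids, n_i),
        "native_language": group,
        "item_id": np.tile(item_ids, n_p),
        "item_language": item_language or group,
        "nasal_first": np.tile(nasal.astype(int), n_p),
        "response": response.ravel(),
        "rt_ms": np.round(rt.ravel(), 1),
    })


def experiment_items(language: str, n_per_cell: int = 50) -> list[tuple[str, int]]:
    """An item list of ``n_per_cell`` nasal-first and ``n_per_cell`` other words."""
    return [(f"{language}_nas{k + 1:03d}", 1) for k in range(n_per_cell)] + \
           [(f"{language}_oth{k + 1:03d}", 0) for k in range(n_per_cell)]


def simulate_experiment(rm: ResponseModel, n_items_per_cell: int = 50,
                        seed: int = 0, crossed: bool = False) -> pd.DataFrame:
    """Simulate a full two-group experiment and return the pooled table.

    Each group rates 2 * ``n_items_per_cell`` items of one language
    (nasal-first and control words in equal number).  With
    ``crossed=False`` groups rate their own language's items; with
    ``crossed=True`` the item languages are swapped (raters judging words
    they cannot know, as when stimuli are foreign words).
    """
    zh_items = experiment_items("zh", n_items_per_cell)
    nl_items = experiment_items("nl", n_items_per_cell)
    ss = np.random.SeedSequence(seed).spawn(2)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    zh_rated, nl_rated = (nl_items, zh_items) if crossed else (zh_items, nl_items)
    tables = [
        generate_responses(rm, zh_rated, "zh", seeds[0],
                           item_language=zh_rated[0][0][:2]),
        generate_responses(rm, nl_rated, "nl", seeds[1],
                           item_language=nl_rated[0][0][:2]),
    ]
    return pd.concat(tables, ignore_index=True)
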