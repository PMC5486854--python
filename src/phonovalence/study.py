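"""Canned study-condition runs for calibration and recovery checks.

These routines fix the simulation conditions of the package's reference
study — lexicons of 5,000 words with a nasal-first valence effect of
|beta| = 0.3 rating points against sigma = 1.5 rating noise (positive in
Mandarin, negative in the Germanic languages), and 2 x 2 rating
experiments with 50 items per cell and 50 participants per group — and
measure how the pipeline behaves on them: chance-level holdout accuracy
under permuted labels, recovery of the planted effect's sign, the Venn
placement of the nasal-first cue, and type-I rate / power of the by-item
interaction test.

Everything is seeded; the same master seed reproduces every number.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .experiment_stats import anova_from_responses, item_means
from .synthetic_data import LexiconModel, ResponseModel, generate_lexicon, simulate_experiment
from .valence_pipeline import (
    feature_scan,
    feature_table,
    permute_labels,
    select_extremes,
    shared_predictors,
    train_evaluate,
)

__all__ = [
    "STUDY_BETAS",
    "study_model",
    "null_calibration",
    "signal_recovery",
    "venn_study",
    "anova_type1_rate",
    "anova_power",
]

# planted nasal-first valence effect per language: positive in Mandarin,
# negative in the Germanic languages
STUDY_BETAS = {"zh": +0.3, "nl": -0.3, "en": -0.3, "de": -0.3}


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def study_model(language: str, seed: int, n_words: int = 5000) -> LexiconModel:
    """The reference lexicon model for one language."""
    return LexiconModel(language, n_words=n_words,
                        nasal_first_effect=STUDY_BETAS[language],
                        valence_sd=1.5, seed=seed)


def null_calibration(seed: int, n_runs: int = 100, n_words: int = 2000,
                     language: str = "nl") -> dict:
    """Mean holdout accuracy over label-permuted runs on one fixed lexicon.

    With the feature-label link destroyed the classifier should score at
    chance; the mean over ``n_runs`` permutations is the calibration number.
    """
    lex_seed, *run_seeds = _child_seeds(seed, n_runs + 1)
    lex = generate_lexicon(study_model(language, lex_seed, n_words))
    ls = select_extremes(lex, 0.2)
    accs = [train_evaluate(permute_labels(ls, s), folds=0, seed=s).holdout_accuracy
            for s in run_seeds]
    return {"mean_accuracy": float(np.mean(accs)), "accuracies": accs,
            "n_runs": n_runs, "n_holdout": int(round(0.3 * len(ls)))}


def signal_recovery(seed: int, n_seeds: int = 100, n_words: int = 5000,
                    holdout_every: int = 2) -> dict:
    """Sign recovery and holdout accuracy under the planted effect.

    ``n_seeds`` lexicons are generated round-robin over the four languages
    at the reference conditions.  For each, the full-lexicon feature scan
    must recover the sign of the planted nasal-first effect; every
    ``holdout_every``-th lexicon is also classified and its holdout
    accuracy recorded.
    """
    languages = list(STUDY_BETAS)
    seeds = _child_seeds(seed, n_seeds)
    recovered = 0
    holdouts = []
    per_language: dict[str, list[int]] = {l: [] for l in languages}
    for k, s in enumerate(seeds):
        lang = languages[k % len(languages)]
        lex = generate_lexicon(study_model(lang, s, n_words))
        tab = feature_table(lex)
        effect = next(e for e in feature_scan(lex, table=tab) if e.name == "nasal_first")
        ok = int(effect.testable and effect.direction == np.sign(STUDY_BETAS[lang]))
        recovered += ok
        per_language[lang].append(ok)
        if k % holdout_every == 0:
            ls = select_extremes(lex, 0.2, table=tab)
            holdouts.append(train_evaluate(ls, folds=0, seed=s).holdout_accuracy)
    return {
        "n_seeds": n_seeds,
        "n_recovered": recovered,
        "recovery_rate": recovered / n_seeds,
        "per_language_rate": {l: float(np.mean(v)) for l, v in per_language.items()},
        "mean_holdout_accuracy": float(np.mean(holdouts)),
        "holdout_accuracies": holdouts,
    }


def venn_study(seed: int, n_words: int = 5000, alpha: float = 0.05):
    """One reference lexicon per language, scanned and intersected."""
    seeds = _child_seeds(seed, len(STUDY_BETAS))
    scans = {}
    for s, lang in zip(seeds, STUDY_BETAS):
        lex = generate_lexicon(study_model(lang, s, n_words))
        scans[lang] = feature_scan(lex)
    return shared_predictors(scans, alpha=alpha)


def anova_type1_rate(seed: int, n_sims: int = 2000, n_items_per_cell: int = 50,
                     alpha: float = 0.05) -> dict:
    """Interaction rejection rate when no crossover exists (gamma = 0)."""
    rm = ResponseModel(gamma=0.0)
    rejections = 0
    for s in _child_seeds(seed, n_sims):
        res = anova_from_responses(simulate_experiment(rm, n_items_per_cell, seed=s))
        rejections += res.interaction.p < alpha
    return {"rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def anova_power(seed: int, n_sims: int = 100, n_items_per_cell: int = 50,
                alpha: float = 0.05, rm: ResponseModel | None = None) -> dict:
    """Interaction detection rate and direction agreement under the default
    crossover magnitude (item-mean cell gaps around 0.3 on the 1-2 scale)."""
    rm = rm or ResponseModel()
    detected = 0
    direction_ok = 0
    for s in _child_seeds(seed, n_sims):
        rt = simulate_experiment(rm, n_items_per_cell, seed=s)
        res = anova_from_responses(rt)
        if res.interaction.p < alpha:
            detected += 1
            im = item_means(rt)
            cell = im.groupby(["native_language", "nasal_first"])["mean_rating"].mean()
            zh_up = cell[("zh", 1)] > cell[("zh", 0)]
            nl_down = cell[("nl", 1)] < cell[("nl", 0)]
            direction_ok += int(zh_up and nl_down)
    return {"power": detected / n_sims, "n_detected": detected,
            "n_direction_ok": direction_ok, "n_sims": n_sims, "alpha": alpha}
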