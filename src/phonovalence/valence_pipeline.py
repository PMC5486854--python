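"""The corpus study: from a valence-rated lexicon to classifiers and scans.

The pipeline mirrors a common extreme-group design in lexical statistics:

* keep only the words in the top and bottom valence quantiles
  (``select_extremes``, default q = 0.2 each side);
* train a classifier on phonological feature vectors to tell the two
  extremes apart, with a stratified 70/30 train/holdout split and ten-fold
  cross-validation inside the training portion (``train_evaluate``);
* on the *full* lexicon, run a per-feature two-sample t-test of valence
  for words with vs. without each feature (``feature_scan``); and
* intersect the significant feature sets across languages
  (``shared_predictors``) to find cues whose predictive value is shared —
  the cross-linguistic Venn diagram.

Features are standardized on the training portion only, so no information
leaks from the holdout into the fit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .feature_extraction import FeatureExtractor, FeatureSchema, build_schema
from .phonology import Transcription, get_inventory, parse_pinyin, parse_transcription

__all__ = [
    "ValenceLexicon",
    "LabeledSet",
    "ClassificationResult",
    "FeatureEffect",
    "VennReport",
    "read_lexicon",
    "write_lexicon",
    "feature_table",
    "select_extremes",
    "permute_labels",
    "train_evaluate",
    "feature_scan",
    "shared_predictors",
    "register_classifier",
]

log = logging.getLogger(__name__)

LEXICON_COLUMNS = ["word", "language", "transcription", "valence"]


@dataclass(frozen=True)
class ValenceLexicon:
    """Word records with transcriptions and 1-9 valence ratings.

    ``data`` has columns word, language, transcription, valence and
    optionally log_frequency; extra columns are carried through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LEXICON_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"lexicon is missing columns {missing}")
        v = self.data["valence"].to_numpy(dtype=float)
        if np.any(v < 1) or np.any(v > 9):
            raise ValueError("valence ratings must lie in [1, 9]")
        if self.data.duplicated(["language", "word"]).any():
            dup = self.data.loc[self.data.duplicated(["language", "word"]), "word"]
            raise ValueError(f"duplicate words within a language: {list(dup[:5])}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def language(self) -> str:
        langs = self.data["language"].unique()
        if len(langs) != 1:
            raise ValueError(f"expected a single-language lexicon, got {sorted(langs)}")
        return langs[0]

    def transcriptions(self) -> list[Transcription]:
        """Parse every row's transcription with the right dialect."""
        lang = self.language
        if lang == "zh":
            return [parse_pinyin(s) for s in self.data["transcription"]]
        inv = get_inventory(lang)
        return [parse_transcription(s, inv) for s in self.data["transcription"]]


def read_lexicon(path) -> ValenceLexicon:
    """Read a TSV lexicon (columns word, language, transcription, valence[, log_frequency])."""
    return ValenceLexicon(pd.read_csv(path, sep="\t"))


def write_lexicon(lex: ValenceLexicon, path) -> None:
    lex.data.to_csv(path, sep="\t", index=False)


def feature_table(lex: ValenceLexicon, schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Per-word feature matrix: word, language, valence, then one column per feature."""
    lang = lex.language
    if schema is None:
        schema = build_schema(lang)
    if schema.language != lang:
        raise ValueError(f"schema language {schema.language!r} != lexicon language {lang!r}")
    extractor = FeatureExtractor(schema)
    rows = [extractor(t).values for t in lex.transcriptions()]
    out = pd.DataFrame(rows, columns=list(schema.names), index=lex.data.index)
    head = lex.data[["word", "language", "valence"]]
    return pd.concat([head, out], axis=1)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# extreme-group labeling


@dataclass(frozen=True)
class LabeledSet:
    """Feature rows for the valence extremes, labeled 1 = positive, 0 = negative."""

    features: pd.DataFrame      # numeric feature columns only
    labels: np.ndarray          # int {0, 1}
    valence: np.ndarray
    words: np.ndarray
    q: float
    n_discarded: int

    def __post_init__(self) -> None:
        pos = self.valence[self.labels == 1]
        neg = self.valence[self.labels == 0]
        if len(pos) and len(neg) and pos.min() < neg.max():
            raise ValueError("label invariant violated: a positive word rates below a negative one")

    def __len__(self) -> int:
        return len(self.labels)


def select_extremes(lex: ValenceLexicon, q: float = 0.2,
                    table: pd.DataFrame | None = None) -> LabeledSet:
    """Label the bottom-q valence quantile negative and the top-q positive.

    The middle of the scale is discarded.  Quantile boundaries are closed:
    ties at a boundary are all included, so the labeled set may slightly
    exceed 2qN.  Identical ratings throughout (coinciding quantiles) are a
    degenerate-input error.

    ``table`` lets a precomputed :func:`feature_table` be reused; otherwise
    one is computed here.
    """
    if not 0 < q < 0.5:
        raise ValueError(f"q must lie in (0, 0.5), got {q}")
    if len(lex) < 10:
        raise ValueError(f"lexicon too small to split into extremes (n={len(lex)})")
    if table is None:
        table = feature_table(lex)
    v = table["valence"].to_numpy(dtype=float)
    lo, hi = np.quantile(v, [q, 1 - q])
    if lo >= hi:
        raise ValueError(f"degenerate valence distribution: quantiles coincide (lo={lo}, hi={hi})")
    neg = v <= lo
    pos = v >= hi
    keep = neg | pos
    feats = table.loc[keep].drop(columns=["word", "language", "valence"]).reset_index(drop=True)
    labels = pos[keep].astype(int)
    n_discarded = int((~keep).sum())
    log.info("select_extremes: q=%s n=%d kept=%d (pos=%d neg=%d) discarded=%d",
             q, len(v), int(keep.sum()), int(pos.sum()), int(neg.sum()), n_discarded)
    return LabeledSet(
        features=feats,
        labels=labels,
        valence=v[keep],
        words=table.loc[keep, "word"].to_numpy(),
        q=q,
        n_discarded=n_discarded,
    )


def permute_labels(ls: LabeledSet, seed: int) -> LabeledSet:
    """Break the feature-label association for a permutation null.

    Labels and valences are permuted *jointly* against the feature rows, so
    the label/valence coupling (and the LabeledSet invariant) is preserved
    while any phonological signal is destroyed.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ls))
    return LabeledSet(
        features=ls.features,
        labels=ls.labels[perm],
        valence=ls.valence[perm],
        words=ls.words,
        q=ls.q,
        n_discarded=ls.n_discarded,
    )


# ---------------------------------------------------------------------------
# classification

_CLASSIFIERS: dict[str, Callable[[], object]] = {
    # linear-kernel SVM at unit regularization, solved in the primal
    # (LinearSVC): same decision rule as SVC(kernel="linear", C=1) here
    # but an order of magnitude faster on lexicon-sized feature tables
    "svm_linear": lambda: LinearSVC(C=1.0, dual="auto", max_iter=10000, random_state=0),
    "svm_linear_kernel": lambda: SVC(kernel="linear", C=1.0),
    "majority": lambda: DummyClassifier(strategy="most_frequent"),
}


def register_classifier(name: str, factory: Callable[[], object]) -> None:
    """Register an additional classifier under ``name`` (pluggable contract)."""
    _CLASSIFIERS[name] = factory


@dataclass(frozen=True)
class ClassificationResult:
    holdout_accuracy: float
    fold_accuracies: tuple[float, ...]
    seed: int
    classifier_name: str
    n_train: int
    n_test: int

    def __post_init__(self) -> None:
        accs = (self.holdout_accuracy, *self.fold_accuracies)
        if any(not 0 <= a <= 1 for a in accs):
            raise ValueError("accuracies must lie in [0, 1]")


def train_evaluate(ls: LabeledSet, train_fraction: float = 0.7, folds: int = 10,
                   classifier: str = "svm_linear", seed: int = 0) -> ClassificationResult:
    """Stratified split, k-fold CV inside the training portion, holdout accuracy.

    The cross-validation happens entirely within the training fraction (a
    model check against overfitting); the classifier is then refit on the
    full training portion and the headline number is the accuracy on the
    untouched holdout.  Standardization is fit on training data only.
    ``folds=0`` skips the cross-validation (the holdout number is
    unaffected), useful in large permutation loops.
    """
    if classifier not in _CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}; have {sorted(_CLASSIFIERS)}")
    y = np.asarray(ls.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present to train a classifier")
    if len(y) < max(folds, 2):
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV, got {len(y)}")
    X = ls.features.to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    model = make_pipeline(StandardScaler(), _CLASSIFIERS[classifier]())
    if folds:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_acc = cross_val_score(clone(model), X_tr, y_tr, cv=cv, scoring="accuracy")
    else:
        fold_acc = np.empty(0)
    model.fit(X_tr, y_tr)
    holdout = float(model.score(X_te, y_te))
    log.info("train_evaluate: clf=%s seed=%d n_train=%d n_test=%d cv_mean=%s holdout=%.4f",
             classifier, seed, len(y_tr), len(y_te),
             f"{fold_acc.mean():.4f}" if len(fold_acc) else "skipped", holdout)
    return ClassificationResult(
        holdout_accuracy=holdout,
        fold_accuracies=tuple(float(a) for a in fold_acc),
        seed=seed,
        classifier_name=classifier,
        n_train=len(y_tr),
        n_test=len(y_te),
    )


# ---------------------------------------------------------------------------
# per-feature valence scan


@dataclass(frozen=True)
class FeatureEffect:
    """Two-sample t of valence for words with vs. without one feature."""

    name: str
    t: float
    df: float
    p: float
    direction: int          # sign of (mean with) - (mean without)
    n_with: int
    n_without: int
    testable: bool = True


def feature_scan(lex: ValenceLexicon, schema: FeatureSchema | None = None,
                 table: pd.DataFrame | None = None,
                 welch: bool = False, fdr: bool = False) -> list[FeatureEffect]:
    """Per-feature valence t-tests over the full lexicon.

    Each feature is dichotomized at presence (> 0) and valence is compared
    between words with and without it.  The default is the pooled-variance
    Student t with df = n_with + n_without - 2; ``welch=True`` switches to
    the unequal-variance form.  Features with an empty group are flagged
    untestable (and excluded from downstream intersections).  No
    multiple-testing correction is applied by default; ``fdr=True`` replaces
    p-values with Benjamini-Hochberg adjusted ones.
    """
    if table is None:
        table = feature_table(lex, schema)
    v = table["valence"].to_numpy(dtype=float)
    names = [c for c in table.columns if c not in ("word", "language", "valence")]
    effects = []
    for name in names:
        x = table[name].to_numpy(dtype=float) > 0
        with_v, without_v = v[x], v[~x]
        n1, n0 = len(with_v), len(without_v)
        if n1 == 0 or n0 == 0:
            effects.append(FeatureEffect(name, np.nan, np.nan, np.nan, 0, n1, n0, testable=False))
            continue
        diff = with_v.mean() - without_v.mean()
        direction = int(np.sign(diff))
        res = stats.ttest_ind(with_v, without_v, equal_var=not welch)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        if not np.isfinite(t):  # zero pooled variance
            df = float(n1 + n0 - 2) if not welch else np.nan
            t, p = (0.0, 1.0) if direction == 0 else (np.inf * direction, 0.0)
        effects.append(FeatureEffect(name, t, df, p, direction, n1, n0))
    untestable = sum(1 for e in effects if not e.testable)
    log.info("feature_scan: n=%d features=%d untestable=%d", len(v), len(effects), untestable)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        testable = [e for e in effects if e.testable]
        adj = multipletests([e.p for e in testable], method="fdr_bh")[1]
        adjusted = {e.name: q for e, q in zip(testable, adj)}
        effects = [
            FeatureEffect(e.name, e.t, e.df, adjusted.get(e.name, np.nan),
                          e.direction, e.n_with, e.n_without, e.testable)
            for e in effects
        ]
    return effects


def effects_frame(effects: Sequence[FeatureEffect]) -> pd.DataFrame:
    """Tabular view of a scan, one row per feature."""
    return pd.DataFrame([e.__dict__ for e in effects])


# ---------------------------------------------------------------------------
# cross-language intersection


@dataclass(frozen=True)
class VennReport:
    """All intersection regions of per-language significant feature sets.

    ``cells`` maps each non-empty language combination (exact region, i.e.
    significant in exactly those languages) to its feature names;
    ``shared_directions`` gives, for each feature in the all-language cell,
    the per-language effect direction.
    """

    languages: tuple[str, ...]
    alpha: float
    significant: Mapping[str, frozenset[str]]
    cells: Mapping[frozenset[str], frozenset[str]]
    shared_directions: Mapping[str, Mapping[str, int]]

    @property
    def shared(self) -> frozenset[str]:
        """Features significant in every language (the central Venn cell)."""
        return self.cells.get(frozenset(self.languages), frozenset())


def shared_predictors(scans: Mapping[str, Sequence[FeatureEffect]],
                      alpha: float = 0.05) -> VennReport:
    """Intersect per-language significant feature sets into a Venn report.

    A feature counts as significant for a language when its scan p-value is
    strictly below ``alpha`` and it was testable there.  Every non-empty
    Venn region is reported; for features shared by all languages the
    per-language direction of the valence effect is attached.
    """
    if len(scans) < 2:
        raise ValueError("need scans from at least two languages")
    for lang, scan in scans.items():
        if not scan:
            raise ValueError(f"empty scan for language {lang!r}")
    languages = tuple(scans)
    sig = {
        lang: frozenset(e.name for e in scan if e.testable and e.p < alpha)
        for lang, scan in scans.items()
    }
    cells: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(languages) + 1):
        for combo in itertools.combinations(languages, r):
            inside = frozenset.intersection(*(sig[l] for l in combo))
            outside = frozenset().union(*(sig[l] for l in languages if l not in combo)) \
                if len(combo) < len(languages) else frozenset()
            cells[frozenset(combo)] = inside - outside
    directions = {}
    for name in cells[frozenset(languages)]:
        directions[name] = {
            lang: next(e.direction for e in scans[lang] if e.name == name)
            for lang in languages
        }
    return VennReport(languages, alpha, sig, cells, directions)
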