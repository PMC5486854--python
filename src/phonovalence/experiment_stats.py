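"""Analysis of the two-alternative valence rating experiments.

The experiments cross two between factors: the rater's native language
(Mandarin vs. Dutch) and whether the rated word begins with a nasal.  Each
trial records a binary judgment (1 = negative, 2 = positive) and a response
time; trials can be missing when the participant does not answer within the
deadline.

The reference analysis is **by item**: responses are averaged within each
word, and the item means enter a 2 (native language) x 2 (nasal-first)
between-items ANOVA with Type-II sums of squares (robust to unbalanced
cells from dropped items) and partial eta-squared effect sizes.  The
crossover signature of interest is the language x nasal-first interaction.
A by-participant aggregation is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "RESPONSE_COLUMNS",
    "AnovaTerm",
    "AnovaResult",
    "read_responses",
    "write_responses",
    "item_means",
    "participant_means",
    "two_way_anova",
    "anova_from_responses",
    "point_biserial",
    "union_probability",
    "summarize_experiment",
]

log = logging.getLogger(__name__)

RESPONSE_COLUMNS = [
    "participant_id", "native_language", "item_id", "item_language",
    "nasal_first", "response", "rt_ms",
]


def validate_responses(rt: pd.DataFrame) -> pd.DataFrame:
    """Check a response table's columns and coding; returns the table."""
    missing = [c for c in RESPONSE_COLUMNS if c not in rt.columns]
    if missing:
        raise ValueError(f"response table is missing columns {missing}")
    resp = rt["response"]
    bad = resp.dropna()[~resp.dropna().isin([1, 2])]
    if len(bad):
        raise ValueError(f"responses must be 1 (negative) or 2 (positive); got {sorted(set(bad))}")
    if (resp.isna() != rt["rt_ms"].isna()).any():
        raise ValueError("response and rt_ms must be missing together")
    per_item = rt.groupby(["native_language", "item_id"])["nasal_first"].nunique()
    if (per_item > 1).any():
        raise ValueError("nasal_first must be constant within an item")
    return rt


def read_responses(path) -> pd.DataFrame:
    """Read a response CSV (empty response/rt fields mean a missed trial)."""
    return validate_responses(pd.read_csv(path))


def write_responses(rt: pd.DataFrame, path) -> None:
    rt.to_csv(path, index=False)


def item_means(rt: pd.DataFrame) -> pd.DataFrame:
    """Per-item mean rating, response count, and missing fraction.

    Missing responses are dropped within each item (listwise); items left
    with zero responses are excluded from the output and counted in
    ``.attrs["n_dropped_items"]`` (and the log).
    """
    if len(rt) == 0:
        raise ValueError("empty response table")
    validate_responses(rt)
    g = rt.groupby(["native_language", "item_id"], sort=True)
    out = g.agg(
        item_language=("item_language", "first"),
        nasal_first=("nasal_first", "first"),
        mean_rating=("response", "mean"),
        n_responses=("response", "count"),
        n_trials=("response", "size"),
    ).reset_index()
    out["missing_fraction"] = 1.0 - out["n_responses"] / out["n_trials"]
    dropped = out["n_responses"] == 0
    n_dropped = int(dropped.sum())
    if n_dropped:
        log.info("item_means: dropped %d item(s) with no responses", n_dropped)
    out = out.loc[~dropped].drop(columns=["n_trials"]).reset_index(drop=True)
    out.attrs["n_dropped_items"] = n_dropped
    return out


def participant_means(rt: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean rating within each nasal-first condition.

    The by-participant unit of analysis: each participant contributes one
    mean per nasal level.  Offered as an alternative to :func:`item_means`;
    the reference path is by item.
    """
    if len(rt) == 0:
        raise ValueError("empty response table")
    validate_responses(rt)
    g = rt.groupby(["native_language", "participant_id", "nasal_first"], sort=True)
    out = g.agg(mean_rating=("response", "mean"),
                n_responses=("response", "count"),
                n_trials=("response", "size")).reset_index()
    out["missing_fraction"] = 1.0 - out["n_responses"] / out["n_trials"]
    out = out.loc[out["n_responses"] > 0].drop(columns=["n_trials"]).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class AnovaTerm:
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float

    def __post_init__(self) -> None:
        expected = self.F * self.df1 / (self.F * self.df1 + self.df2)
        if not np.isclose(self.eta_p2, expected, atol=1e-10):
            raise ValueError("eta_p2 inconsistent with F and degrees of freedom")


@dataclass(frozen=True)
class AnovaResult:
    """F, p and partial eta-squared for the two mains and the interaction."""

    language: AnovaTerm
    nasal_first: AnovaTerm
    interaction: AnovaTerm
    n_units: int

    def term(self, name: str) -> AnovaTerm:
        return {"language": self.language, "nasal_first": self.nasal_first,
                "interaction": self.interaction}[name]


def two_way_anova(items: pd.DataFrame, value: str = "mean_rating") -> AnovaResult:
    """2 (native language) x 2 (nasal-first) between-units ANOVA.

    ``items`` is the output of :func:`item_means` (or
    :func:`participant_means`).  Sums of squares are Type II, appropriate
    for unbalanced cells; partial eta-squared is SS_term / (SS_term +
    SS_residual) = F*df1 / (F*df1 + df2).  All four design cells must be
    non-empty.
    """
    needed = {"native_language", "nasal_first", value}
    if not needed <= set(items.columns):
        raise ValueError(f"need columns {sorted(needed)}")
    counts = items.groupby(["native_language", "nasal_first"]).size()
    langs = items["native_language"].unique()
    levels = items["nasal_first"].unique()
    if len(langs) != 2 or len(levels) != 2:
        raise ValueError(
            f"need 2 languages x 2 nasal levels, got {sorted(langs)} x {sorted(levels)}"
        )
    for lang in langs:
        for lev in levels:
            if (lang, lev) not in counts.index:
                raise ValueError(f"empty design cell: language={lang!r}, nasal_first={lev!r}")

    d = items.rename(columns={value: "y"})
    fit = smf.ols("y ~ C(native_language) * C(nasal_first)", data=d).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df2 = int(table.loc["Residual", "df"])

    def make(term: str) -> AnovaTerm:
        ss = float(table.loc[term, "sum_sq"])
        df1 = int(table.loc[term, "df"])
        F = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        return AnovaTerm(F=F, df1=df1, df2=df2, p=p, eta_p2=ss / (ss + ss_resid))

    return AnovaResult(
        language=make("C(native_language)"),
        nasal_first=make("C(nasal_first)"),
        interaction=make("C(native_language):C(nasal_first)"),
        n_units=len(items),
    )


def anova_from_responses(rt: pd.DataFrame, by: str = "item") -> AnovaResult:
    """Aggregate a raw response table and run the 2x2 ANOVA on the means."""
    if by == "item":
        return two_way_anova(item_means(rt))
    if by == "participant":
        return two_way_anova(participant_means(rt))
    raise ValueError(f"by must be 'item' or 'participant', got {by!r}")


def point_biserial(items: pd.DataFrame, within_language: str) -> tuple[float, float]:
    """Correlation of item mean ratings with the binary nasal-first cue.

    Pearson (equivalently point-biserial) correlation across the items of
    one language group, with a two-sided p-value.
    """
    d = items[items["native_language"] == within_language]
    if len(d) < 3:
        raise ValueError(f"need at least 3 items for {within_language!r}, got {len(d)}")
    x = d["nasal_first"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("both nasal-first levels must be present")
    r, p = stats.pearsonr(x, d["mean_rating"].to_numpy(dtype=float))
    return float(r), float(p)


def union_probability(p_a: float, p_b: float) -> float:
    """P(A or B) for independent cues: p_a + p_b - p_a * p_b.

    The back-of-envelope combination argument: two independent cues that
    each predict valence slightly above chance predict it considerably
    better jointly.
    """
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return p_a + p_b - p_a * p_b


def summarize_experiment(rt: pd.DataFrame) -> pd.DataFrame:
    """Descriptives per language group: missingness, positivity, RT.

    Returns one row per native language with the fraction of missed trials,
    the fraction of positive (=2) judgments among answered trials (absent
    when nothing was answered), and mean/SD response time.
    """
    validate_responses(rt)
    rows = []
    for lang, d in rt.groupby("native_language", sort=True):
        answered = d["response"].notna()
        n_ans = int(answered.sum())
        rows.append({
            "native_language": lang,
            "n_trials": len(d),
            "missing_fraction": 1.0 - n_ans / len(d),
            "positive_fraction": float((d.loc[answered, "response"] == 2).mean())
            if n_ans else np.nan,
            "rt_mean_ms": float(d.loc[answered, "rt_ms"].mean()) if n_ans else np.nan,
            "rt_sd_ms": float(d.loc[answered, "rt_ms"].std(ddof=1)) if n_ans > 1 else np.nan,
        })
    return pd.DataFrame(rows)
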