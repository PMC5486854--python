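"""By-item aggregation, the 2x2 ANOVA, correlations and descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phonovalence import (
    ResponseModel,
    anova_from_responses,
    generate_responses,
    item_means,
    participant_means,
    point_biserial,
    simulate_experiment,
    summarize_experiment,
    two_way_anova,
    union_probability,
)
from phonovalence.experiment_stats import AnovaTerm


def make_table(rows):
    return pd.DataFrame(rows, columns=[
        "participant_id", "native_language", "item_id", "item_language",
        "nasal_first", "response", "rt_ms"])


def items_frame(cells):
    """Build an item-means frame from {(language, nasal): [values]}."""
    rows = []
    for (lang, nas), values in cells.items():
        for k, v in enumerate(values):
            rows.append({"native_language": lang, "item_id": f"{lang}{nas}_{k}",
                         "item_language": lang, "nasal_first": nas,
                         "mean_rating": float(v), "n_responses": 10,
                         "missing_fraction": 0.0})
    return pd.DataFrame(rows)


class TestItemMeans:
    def test_mean_and_missing_fraction(self):
        rt = make_table([
            ("p1", "zh", "i1", "zh", 1, 2, 700.0),
            ("p2", "zh", "i1", "zh", 1, 2, 710.0),
            ("p3", "zh", "i1", "zh", 1, 1, 650.0),
            ("p4", "zh", "i1", "zh", 1, np.nan, np.nan),
        ])
        out = item_means(rt)
        assert len(out) == 1
        assert out.loc[0, "mean_rating"] == pytest.approx(5 / 3)
        assert out.loc[0, "missing_fraction"] == 0.25
        assert out.loc[0, "n_responses"] == 3

    def test_fully_missing_item_dropped_and_counted(self):
        rt = make_table([
            ("p1", "zh", "i1", "zh", 1, 2, 700.0),
            ("p1", "zh", "i2", "zh", 0, np.nan, np.nan),
            ("p2", "zh", "i2", "zh", 0, np.nan, np.nan),
        ])
        out = item_means(rt)
        assert list(out["item_id"]) == ["i1"]
        assert out.attrs["n_dropped_items"] == 1

    def test_row_order_invariance(self):
        rows = [("p%d" % k, "nl", "i%d" % (k % 3), "nl", (k % 3) % 2,
                 1 + (k % 2), 600.0 + k) for k in range(12)]
        a = item_means(make_table(rows))
        b = item_means(make_table(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_inconsistent_nasal_coding_rejected(self):
        rt = make_table([
            ("p1", "zh", "i1", "zh", 1, 2, 700.0),
            ("p2", "zh", "i1", "zh", 0, 1, 700.0),
        ])
        with pytest.raises(ValueError, match="constant within an item"):
            item_means(rt)


class TestTwoWayAnova:
    def test_identical_cell_means_give_zero_interaction(self):
        items = items_frame({
            ("zh", 1): [1.4, 1.6], ("zh", 0): [1.4, 1.6],
            ("nl", 1): [1.4, 1.6], ("nl", 0): [1.4, 1.6],
        })
        res = two_way_anova(items)
        assert res.interaction.F == pytest.approx(0.0, abs=1e-12)
        assert res.language.F == pytest.approx(0.0, abs=1e-12)

    def test_balanced_design_matches_closed_form(self):
        """Two observations per cell; F terms computed by the textbook
        balanced two-way formulas inside the test."""
        cells = {("zh", 1): [2.0, 4.0], ("zh", 0): [1.0, 3.0],
                 ("nl", 1): [1.0, 1.0], ("nl", 0): [3.0, 5.0]}
        y = {k: np.array(v) for k, v in cells.items()}
        grand = np.mean([v for vv in cells.values() for v in vv])
        mean_lang = {l: np.concatenate([y[(l, 1)], y[(l, 0)]]).mean() for l in ("zh", "nl")}
        mean_nas = {n: np.concatenate([y[("zh", n)], y[("nl", n)]]).mean() for n in (0, 1)}
        ss_a = 4 * sum((m - grand) ** 2 for m in mean_lang.values())
        ss_b = 4 * sum((m - grand) ** 2 for m in mean_nas.values())
        ss_ab = 2 * sum(
            (y[(l, n)].mean() - mean_lang[l] - mean_nas[n] + grand) ** 2
            for l in ("zh", "nl") for n in (0, 1))
        ss_e = sum(((y[k] - y[k].mean()) ** 2).sum() for k in cells)
        res = two_way_anova(items_frame(cells))
        assert res.language.F == pytest.approx(ss_a / (ss_e / 4))
        assert res.nasal_first.F == pytest.approx(ss_b / (ss_e / 4))
        assert res.interaction.F == pytest.approx(ss_ab / (ss_e / 4))
        assert res.interaction.df1 == 1 and res.interaction.df2 == 4
        assert res.interaction.eta_p2 == pytest.approx(ss_ab / (ss_ab + ss_e))

    def test_crossover_gives_interaction_the_largest_f(self):
        """zh raises nasal-first items, nl lowers them: across simulated
        replicates the interaction F dominates both main effects."""
        rng = np.random.default_rng(8)
        wins = 0
        for _ in range(50):
            cells = {
                ("zh", 1): 1.8 + rng.normal(0, 0.08, 20),
                ("zh", 0): 1.4 + rng.normal(0, 0.08, 20),
                ("nl", 1): 1.4 + rng.normal(0, 0.08, 20),
                ("nl", 0): 1.8 + rng.normal(0, 0.08, 20),
            }
            res = two_way_anova(items_frame(cells))
            wins += res.interaction.F > max(res.language.F, res.nasal_first.F)
        assert wins == 50

    def test_matches_pingouin_on_unbalanced_design(self):
        """Independent oracle: pingouin's two-way ANOVA (Type II) on an
        unbalanced items table gives the same F, p and partial eta-squared."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        cells = {("zh", 1): rng.normal(1.6, 0.1, 47), ("zh", 0): rng.normal(1.5, 0.1, 50),
                 ("nl", 1): rng.normal(1.4, 0.1, 44), ("nl", 0): rng.normal(1.55, 0.1, 50)}
        items = items_frame(cells)
        res = two_way_anova(items)
        pg = pingouin.anova(data=items, dv="mean_rating",
                            between=["native_language", "nasal_first"]).set_index("Source")
        inter = pg.loc["native_language * nasal_first"]
        assert res.interaction.F == pytest.approx(float(inter["F"]), rel=1e-6)
        assert res.interaction.p == pytest.approx(float(inter["p_unc"]), rel=1e-6)
        assert res.interaction.eta_p2 == pytest.approx(float(inter["np2"]), rel=1e-4)

    def test_response_shift_leaves_f_unchanged(self):
        rng = np.random.default_rng(4)
        cells = {(l, n): rng.normal(1.5, 0.1, 15) for l in ("zh", "nl") for n in (0, 1)}
        res1 = two_way_anova(items_frame(cells))
        shifted = {k: v + 7.0 for k, v in cells.items()}
        res2 = two_way_anova(items_frame(shifted))
        for term in ("language", "nasal_first", "interaction"):
            assert res1.term(term).F == pytest.approx(res2.term(term).F)

    def test_empty_cell_named_in_error(self):
        items = items_frame({("zh", 1): [1.5, 1.6], ("zh", 0): [1.4, 1.5],
                             ("nl", 1): [1.5, 1.4]})
        with pytest.raises(ValueError, match="2 languages x 2 nasal levels|empty design cell"):
            two_way_anova(items)
        items_4 = items_frame({("zh", 1): [1.5], ("zh", 0): [1.4],
                               ("nl", 1): [1.5], ("nl", 0): []})
        # an empty list contributes no rows: the nl/0 cell is missing
        with pytest.raises(ValueError):
            two_way_anova(items_4)

    def test_eta_identity_enforced_by_type(self):
        with pytest.raises(ValueError, match="eta_p2"):
            AnovaTerm(F=10.0, df1=1, df2=100, p=0.001, eta_p2=0.5)
        t = AnovaTerm(F=10.0, df1=1, df2=100, p=0.001, eta_p2=10.0 / 110.0)
        assert t.eta_p2 == pytest.approx(t.F * t.df1 / (t.F * t.df1 + t.df2))


class TestPointBiserial:
    def test_perfect_separation_gives_unit_correlation(self):
        items = items_frame({("zh", 1): [2.0] * 5, ("zh", 0): [1.0] * 5})
        r, p = point_biserial(items, "zh")
        assert r == pytest.approx(1.0)

    def test_permutation_null_centers_at_zero(self):
        """Permuting the nasal labels across items yields r centered at 0."""
        rng = np.random.default_rng(6)
        items = items_frame({("zh", 1): rng.normal(1.7, 0.1, 25),
                             ("zh", 0): rng.normal(1.3, 0.1, 25)})
        x = items["nasal_first"].to_numpy(float)
        y = items["mean_rating"].to_numpy(float)
        rs = []
        for _ in range(1000):
            perm = rng.permutation(x)
            rs.append(stats.pearsonr(perm, y)[0])
        assert abs(np.mean(rs)) < 0.02
        r, _ = point_biserial(items, "zh")
        assert r > np.quantile(rs, 0.999)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(7)
        hi, lo = rng.normal(1.7, 0.1, 20), rng.normal(1.3, 0.1, 20)
        r1, _ = point_biserial(items_frame({("zh", 1): hi, ("zh", 0): lo}), "zh")
        r2, _ = point_biserial(items_frame({("zh", 1): lo, ("zh", 0): hi}), "zh")
        assert r1 == pytest.approx(-r2)
        assert r1 > 0 > r2

    def test_single_level_rejected(self):
        items = items_frame({("zh", 1): [1.5, 1.6, 1.7]})
        with pytest.raises(ValueError, match="both nasal-first levels"):
            point_biserial(items, "zh")


class TestUnionProbability:
    def test_two_weak_cues_combine(self):
        assert union_probability(0.55, 0.55) == pytest.approx(0.7975)

    @pytest.mark.parametrize("pa, pb, expected", [
        (0.0, 0.3, 0.3), (1.0, 0.3, 1.0), (0.3, 0.4, 0.58)])
    def test_boundary_identities_and_hand_case(self, pa, pb, expected):
        assert union_probability(pa, pb) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p_a"):
            union_probability(1.2, 0.5)
        with pytest.raises(ValueError, match="p_b"):
            union_probability(0.5, -0.1)


class TestSummarize:
    def test_constructed_missing_and_positive_fractions(self):
        """1,000 trials, 7 missing, 601 positive among the rest: 0.7% missing
        and 60.5% positive."""
        rows = []
        for k in range(1000):
            if k < 7:
                resp, rt = np.nan, np.nan
            elif k < 7 + 601:
                resp, rt = 2, 700.0
            else:
                resp, rt = 1, 700.0
            rows.append(("p1", "zh", f"i{k}", "zh", 0, resp, rt))
        out = summarize_experiment(make_table(rows)).set_index("native_language")
        assert out.loc["zh", "missing_fraction"] == pytest.approx(0.007)
        assert out.loc["zh", "positive_fraction"] == pytest.approx(601 / 993)
        assert round(100 * out.loc["zh", "positive_fraction"], 1) == 60.5

    def test_all_missing_group_reports_absent_fractions(self):
        rows = [("p1", "zh", f"i{k}", "zh", 0, np.nan, np.nan) for k in range(5)]
        out = summarize_experiment(make_table(rows))
        assert np.isnan(out.loc[0, "positive_fraction"])
        assert out.loc[0, "missing_fraction"] == 1.0

    def test_constant_rt_gives_zero_sd(self):
        rows = [("p1", "nl", f"i{k}", "nl", 0, 2, 650.0) for k in range(4)]
        out = summarize_experiment(make_table(rows))
        assert out.loc[0, "rt_mean_ms"] == 650.0
        assert out.loc[0, "rt_sd_ms"] == 0.0


class TestEndToEnd:
    def test_by_item_and_by_participant_agree_on_direction(self):
        rt = simulate_experiment(ResponseModel(), n_items_per_cell=50, seed=11)
        by_item = anova_from_responses(rt, by="item")
        by_part = anova_from_responses(rt, by="participant")
        assert by_item.interaction.p < 0.001
        assert by_part.interaction.p < 0.001
        im = item_means(rt)
        r_zh, _ = point_biserial(im, "zh")
        r_nl, _ = point_biserial(im, "nl")
        assert r_zh > 0 > r_nl

    def test_eta_identity_on_simulated_experiment(self):
        rt = simulate_experiment(ResponseModel(), n_items_per_cell=30, seed=12)
        res = anova_from_responses(rt)
        for term in ("language", "nasal_first", "interaction"):
            t = res.term(term)
            assert t.eta_p2 == pytest.approx(t.F * t.df1 / (t.F * t.df1 + t.df2), abs=1e-12)
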