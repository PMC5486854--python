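"""Simulate a two-group rating experiment and run the by-item analysis.

Fifty Mandarin and fifty Dutch speakers each judge 100 words (half
nasal-first) as positive or negative under a response deadline.  The
generator plants a crossover: nasal-first words pull Mandarin speakers
toward 'positive' and Dutch speakers toward 'negative'.  The analysis
averages responses within items and fits a 2 (native language) x 2
(nasal-first) between-items ANOVA with partial eta-squared.
"""

from phonovalence import (
    ResponseModel,
    anova_from_responses,
    item_means,
    point_biserial,
    simulate_experiment,
    summarize_experiment,
    union_probability,
)

rt = simulate_experiment(ResponseModel(), n_items_per_cell=50, seed=99)
print(summarize_experiment(rt).to_string(index=False))
print("(missing = deadline misses; ratings are 1 = negative, 2 = positive)\n")

res = anova_from_responses(rt, by="item")
for term in ("language", "nasal_first", "interaction"):
    t = res.term(term)
    print(f"{term:12s} F({t.df1}, {t.df2}) = {t.F:8.2f}, p = {t.p:.3g}, "
          f"partial eta^2 = {t.eta_p2:.3f}")

im = item_means(rt)
r_zh, p_zh = point_biserial(im, "zh")
r_nl, p_nl = point_biserial(im, "nl")
print(f"\nitem-level correlation of mean rating with nasal-first:")
print(f"  Mandarin raters r = {r_zh:+.3f} (p = {p_zh:.2g});"
      f"  Dutch raters r = {r_nl:+.3f} (p = {p_nl:.2g})")
print("The interaction term carries the crossover: the same cue shifts the")
print("two groups in opposite directions.")

print(f"\nTwo independent 55%-accurate cues combined:"
      f" P(A or B) = {union_probability(0.55, 0.55):.4f} (~80%)")
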