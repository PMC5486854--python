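"""The corpus study on synthetic lexicons: classify extremes, scan, intersect.

Generates a 5,000-word valence lexicon per language with a planted
nasal-first effect (+0.3 rating points in Mandarin, -0.3 in Dutch, English
and German, against 1.5 points of rating noise), trains a linear SVM to
separate the top and bottom valence quintiles, t-tests every feature on
the full lexicon, and intersects the significant features across the four
languages.
"""

from phonovalence import feature_scan, feature_table, select_extremes, shared_predictors, train_evaluate
from phonovalence.study import STUDY_BETAS, study_model
from phonovalence.synthetic_data import generate_lexicon

scans = {}
for i, (lang, beta) in enumerate(STUDY_BETAS.items()):
    lex = generate_lexicon(study_model(lang, seed=42 + i, n_words=5000))
    tab = feature_table(lex)
    ls = select_extremes(lex, q=0.2, table=tab)
    res = train_evaluate(ls, seed=42)
    scans[lang] = feature_scan(lex, table=tab)
    nf = next(e for e in scans[lang] if e.name == "nasal_first")
    print(f"{lang}: beta={beta:+.1f}  n_extremes={len(ls)}  "
          f"holdout acc={res.holdout_accuracy:.3f}  "
          f"cv mean={sum(res.fold_accuracies)/10:.3f}  "
          f"nasal_first: t({nf.df:.0f})={nf.t:+.2f}, p={nf.p:.2g}")

print("\nHoldout accuracies in the low-to-mid 50s reflect a real but small")
print("phonological signal; the scan's t recovers its sign per language.")

report = shared_predictors(scans, alpha=0.05)
print(f"\nFeatures significant in all four languages: {sorted(report.shared)}")
d = report.shared_directions["nasal_first"]
print("nasal_first directions:", {l: ("+" if s > 0 else "-") for l, s in d.items()},
      "-> the same cue predicts positive valence in Mandarin and negative")
print("valence in the Germanic languages, the crossover of interest.")
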