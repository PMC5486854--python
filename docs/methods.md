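# Methods

This note documents the models, defaults and design decisions behind
`phonovalence`: what each stage computes, which knobs matter, what the
synthetic generators do and do not emulate, and where genuinely open
choices were resolved.

## Phonological substrate

**Inventories.** Each language ships a compact research inventory
(35–43 symbols) as an editable TSV: segmental symbols annotated with
sound class, manner, place, voicing, vowel height/backness, rounding,
length and diphthong status. These are deliberately not exhaustive
phonologies — the feature schema only consumes articulatory *class
memberships* — but they respect the class contrasts that differ across
the four languages: dental fricatives appear only in English, an alveolar
trill and a uvular only in Dutch and German, and lexical tone only in
Mandarin (carried on the transcription, not the segment).

**Transcription dialects.** Pronunciation databases with their own
internal coding are licensed, so the package defines two reproducible
dialects. The *whitespace dialect* (en/nl/de) is a space-separated symbol
string; parsing is total over the inventory and an unmapped symbol is an
error naming the token and position, never a silent skip. The *Pinyin
dialect* (zh) is strict: each syllable is an initial+final romanisation
with a mandatory trailing tone digit 1–5 (5 = neutral); diacritics are
rejected. Initials match longest-first and the remainder must be a known
final, so parses are unambiguous.

**Syllabification.** For unboundaried input, segmentation follows the
maximal-onset principle against a per-language legal-onset list shipped
as data: each intervocalic consonant cluster donates its longest suffix
that is a legal onset to the following syllable. This is deterministic
(no ties by construction). Pinyin input keeps its syllable boundaries
verbatim. Sequencing invariants — syllables concatenate back to the
phoneme string, every nucleus is non-empty — are property-tested on
thousands of random words. How any particular licensed database cuts
syllables is unknowable here; maximal onset is the documented stand-in.

## Feature schema

The master list contains exactly 105 named features (a data file,
`data/feature_specs.tsv`) in five families:

1. *word counts* — phonemes matching a class predicate (7 manners,
   9 places, voiced consonants, plus totals: phonemes, syllables, vowels,
   consonants and vowel-class counts);
2. *word proportions* — the same counts divided by word length;
3. *onset* — class counts restricted to the first syllable;
4. *first consonant* — indicators for the word-initial phoneme's class
   (`nasal_first` is the one of primary interest);
5. *vowels/tone* — indicator banks for the first vowel's height,
   backness, rounding, length and diphthong status, and for Mandarin the
   first syllable's tone (five indicators) plus a mean-tone level.

The exact composition of any historically used feature set of this size
is not recoverable; this enumeration is the package's own documented
surrogate, chosen as the natural cross-product of class predicates and
families, constrained to 105 entries and kept editable. Per-language
schemas are subsets (en 91, nl/de 95, zh 89): dental features are
English-only; trill and uvular features Dutch/German; tone Mandarin; the
close-mid/open-mid and near-front/near-back vowel distinctions are absent
from Mandarin.

Interpretation decisions: "nasal-first" means the *word-initial phoneme*
is a nasal consonant (vowel-initial words score 0 on all first-consonant
indicators, keeping vectors dense); first-syllable counts use the
syllabifier's first syllable; proportions satisfy
`proportion × word length = count` exactly. Extraction is verified
feature-by-feature against an independent naive re-scan on 1,000 random
words per language.

## Corpus pipeline

**Extreme-group design.** The bottom and top q-quantiles of the valence
distribution (default q = 0.2) are labeled negative/positive; the middle
is discarded. Quantile boundaries are closed — ties are all included, so
the labeled set can slightly exceed 2qN — making the selection
deterministic and row-order invariant. A lexicon with coinciding
quantiles (e.g. constant valence) is a degenerate-input error.

**Classification.** The headline number is holdout accuracy: a
stratified 70/30 split by seed, features standardized on the training
portion only (no leakage), ten-fold cross-validation *inside* the
training portion as an overfitting check, then a refit on the full
training portion scored once on the untouched 30%. The default
classifier is a linear-kernel SVM at unit regularization (C = 1), solved
in the primal (`LinearSVC`); the kernelized solver is registered as
`svm_linear_kernel` and a majority-class baseline as `majority`, and the
registry is pluggable — different linear-margin solvers give
near-identical accuracy on these feature tables, so a single SVM plus a
baseline suffices.

**Per-feature scans.** Run on the *full* lexicon, not the extremes: each
feature is dichotomized at presence (> 0) and valence compared between
words with and without it by the pooled-variance Student t with
df = n₁ + n₂ − 2 (this df convention is what makes the degrees of
freedom track lexicon size − 2). Welch's form is available behind a
flag. Features with an empty group are flagged untestable and excluded
from intersections. No multiple-testing correction is applied by default
(the Venn intersections are defined on raw p < α); Benjamini–Hochberg is
available behind a flag.

**Cross-language intersection.** Per language, the significant feature
set at α (default 0.05); the report enumerates every exact Venn region
and attaches per-language effect directions for the all-language cell.

## Experiment analysis

**Unit of analysis.** The reference path is *by item*: responses are
averaged within each word (listwise deletion of missed trials; items
losing all responses are dropped and counted), giving error degrees of
freedom of (number of analyzed items − 4) in the 2×2 design — 196 for
200 items. A by-participant aggregation is provided as an option.

**ANOVA.** The item means enter an ordinary least-squares 2 (native
language) × 2 (nasal-first) between-items ANOVA with Type-II sums of
squares, the standard choice for unbalanced factorial designs (items can
be lost wholesale). Partial eta-squared is SS_term/(SS_term + SS_resid),
identically F·df₁/(F·df₁ + df₂) — an identity enforced by the result
type. Ratings are kept on the printed 1–2 coding; all F statistics are
invariant to shifting the coding. The statsmodels OLS/ANOVA machinery
performs the fit; an independent cross-check against pingouin's
implementation runs in the test suite.

**Correlations and descriptives.** The point-biserial correlation is the
Pearson correlation of item mean ratings with the binary nasal-first
indicator within one language group (computed over items, which is the
natural unit once ratings are item means). Descriptives report missing
fraction, positive fraction among answered trials, and RT mean/SD per
group. `union_probability` implements the inclusion–exclusion
combination for independent cues, p_A + p_B − p_A·p_B: two 55%-accurate
cues jointly give 0.7975 ≈ 80%.

## Synthetic generators

**Lexicons.** Words are sampled as legal syllable sequences from the
language's inventory: onsets from the legal-onset list, single-vowel
nuclei, codas from a small per-language repertoire; Mandarin words are
sampled as initial+final+tone syllables and stored in the Pinyin dialect.
Word-initial nasality is forced at `nasal_first_rate` (default 0.25).
Valence is μ + β·nasal_first + N(0, σ) clipped to [1, 9]. Defaults:
μ = 5, σ = 1.5, |β| = 0.3 — i.e. a ≈ 0.2 SD group difference, the small
effect size whose classification signature is holdout accuracy in the
low-to-mid 50s — with β > 0 for Mandarin-like and β < 0 for Germanic-like
lexicons; words are mostly two syllables (mean ≈ 2.15), with reference
lexicons of 5,000 words. What the generator does *not* emulate:
morphology, frequency–valence covariation, semantic structure, or any
real language's phonotactic statistics beyond onset legality. Passing
recovery tests therefore shows the *pipeline* is sound and calibrated,
not that any real lexicon carries the effect.

**Experiments.** Each trial's probability of a positive judgment is
logistic(α_group + s·γ·nasal_first + participant effect + item effect)
with s = +1 for Mandarin and −1 for Dutch raters; random effects are
additive on the log-odds scale (participant and item SDs 0.5 and 0.3),
trials go missing at rate 0.007, whole items can be dropped via
`item_dropout`, and RTs are lognormal (median ≈ 713 ms, matching fast
binary judgments). Defaults α = 0.2, γ = 1.4 produce item-mean cell gaps
of ≈ 0.3 on the 1–2 scale. Because the nasal term enters uncentered, the
crossover also induces a group-mean difference (a language main effect);
the analysis target — the interaction term — is unaffected, and the
calibration studies test only that term.

## Calibration studies (`phonovalence.study`)

Fixed reference conditions, all seeded: (a) *null calibration* — mean
holdout accuracy over 100 label-permuted classifier runs on a fixed
2,000-word lexicon, expected within [0.48, 0.52]; permutations shuffle
labels and valences jointly against the feature rows so only the
phonology–label link is destroyed; (b) *signal recovery* — 100 lexicons
of 5,000 words at |β| = 0.3, σ = 1.5 (round-robin over the four
languages): the scan must recover sign(β) for `nasal_first` in ≥ 95, and
mean holdout accuracy (measured on 50 of the runs) must exceed the
permutation band; (c) *Venn placement* — one lexicon per language;
`nasal_first` must land in the all-language cell with directions
(+, −, −, −); (d) *ANOVA calibration* — with γ = 0 the interaction's
rejection rate at α = 0.05 over 2,000 simulated experiments should lie
in [0.04, 0.06]; at the default crossover (50 items/cell,
50 participants/group) detection power should reach ≥ 80% with the
planted direction in every detection. `scripts/acceptance.py` runs all
of these from one master seed; problem sizes (2,000/5,000-word lexicons,
100-seed batches, 2,000 null simulations) are the package's reference
scales, chosen to pin each rate to roughly ±1 percentage point of Monte
Carlo error.

## Numerical and degenerate-case conventions

Zero-variance t-tests: if both groups are constant, t = ±∞ with p = 0
when means differ and t = 0 with p = 1 when they agree (the scipy
statistic is patched only in these cases). Constant features: one group
is empty, hence untestable. Vowel-free transcriptions cannot be
syllabified (error); vowel-only words have all first-consonant
indicators 0. Tone features evaluate to 0 for toneless transcriptions of
Mandarin words, which the generator never produces. Valence clipping at
the scale edges slightly shrinks extreme tails at large σ; at the
default σ = 1.5 around μ = 5 the effect is negligible.

## Known limitations

Inventories and onset lists are small research approximations, not
reference phonologies; the 105-feature list is a surrogate enumeration;
the Pinyin dialect accepts some phonotactically illegal but structurally
well-formed syllables (e.g. unusual initial–final combinations); the
experiment generator draws independent trials given the random effects
(no sequential or fatigue structure); and nothing here bears on *why* a
nasal onset would attract opposite valence in different language
families — the package measures, it does not explain.
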