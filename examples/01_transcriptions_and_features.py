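"""Parse transcriptions in both dialects and read off phonological features.

Builds two small words — Dutch /man/ in the whitespace symbol dialect and
Mandarin "bei1 shang1" in numeric-tone Pinyin — and shows the phoneme
sequences, syllable cuts, and a few entries of their feature vectors.
"""

from phonovalence import (
    build_schema,
    extract_features,
    get_inventory,
    nasal_first,
    parse_pinyin,
    parse_transcription,
    syllabify,
)

nl = get_inventory("nl")
man = parse_transcription("m a n", nl)
print("Dutch /man/  phonemes:", " ".join(man.symbols))
print("  first phoneme:", man.phonemes[0].manner, man.phonemes[0].place,
      "-> nasal_first =", nasal_first(man))

manda = parse_transcription("m a n d a", nl)
sylls = syllabify(manda, nl)
print("Dutch /manda/ syllabified:",
      ".".join("".join(p.symbol for p in s.phonemes) for s in sylls),
      "(maximal onset: /nd/ is not a legal Dutch onset, /d/ is)")

zh = parse_pinyin("bei1 shang1")
print("Mandarin 'bei1 shang1'  phonemes:", " ".join(zh.symbols),
      " tones:", zh.tones)

schema = build_schema("nl")
vec = extract_features(man, schema)
print(f"\nDutch schema has {len(schema)} features (master list: 105).")
for name in ("nasal_count", "nasal_proportion", "onset_nasal_count",
             "nasal_first", "first_vowel_height_open"):
    print(f"  {name:26s} = {vec.values[schema.index(name)]:.3f}")
print("Counts, proportions and indicators above are the raw ingredients the")
print("valence classifier and the per-feature scans consume.")
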