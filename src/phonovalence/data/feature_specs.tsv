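name	family	predicate	statistic	languages
nasal_count	word_count	manner=nasal	count	en,nl,de,zh
plosive_count	word_count	manner=plosive	count	en,nl,de,zh
fricative_count	word_count	manner=fricative	count	en,nl,de,zh
affricate_count	word_count	manner=affricate	count	en,nl,de,zh
approximant_count	word_count	manner=approximant	count	en,nl,de,zh
lateral_count	word_count	manner=lateral	count	en,nl,de,zh
trill_count	word_count	manner=trill	count	nl,de
bilabial_count	word_count	place=bilabial	count	en,nl,de,zh
labiodental_count	word_count	place=labiodental	count	en,nl,de,zh
dental_count	word_count	place=dental	count	en
alveolar_count	word_count	place=alveolar	count	en,nl,de,zh
postalveolar_count	word_count	place=postalveolar	count	en,nl,de,zh
palatal_count	word_count	place=palatal	count	en,nl,de,zh
velar_count	word_count	place=velar	count	en,nl,de,zh
uvular_count	word_count	place=uvular	count	nl,de
glottal_count	word_count	place=glottal	count	en,nl,de,zh
voiced_count	word_count	voiced_consonant	count	en,nl,de,zh
nasal_proportion	word_proportion	manner=nasal	proportion	en,nl,de,zh
plosive_proportion	word_proportion	manner=plosive	proportion	en,nl,de,zh
fricative_proportion	word_proportion	manner=fricative	proportion	en,nl,de,zh
affricate_proportion	word_proportion	manner=affricate	proportion	en,nl,de,zh
approximant_proportion	word_proportion	manner=approximant	proportion	en,nl,de,zh
lateral_proportion	word_proportion	manner=lateral	proportion	en,nl,de,zh
trill_proportion	word_proportion	manner=trill	proportion	nl,de
bilabial_proportion	word_proportion	place=bilabial	proportion	en,nl,de,zh
labiodental_proportion	word_proportion	place=labiodental	proportion	en,nl,de,zh
dental_proportion	word_proportion	place=dental	proportion	en
alveolar_proportion	word_proportion	place=alveolar	proportion	en,nl,de,zh
postalveolar_proportion	word_proportion	place=postalveolar	proportion	en,nl,de,zh
palatal_proportion	word_proportion	place=palatal	proportion	en,nl,de,zh
velar_proportion	word_proportion	place=velar	proportion	en,nl,de,zh
uvular_proportion	word_proportion	place=uvular	proportion	nl,de
glottal_proportion	word_proportion	place=glottal	proportion	en,nl,de,zh
voiced_proportion	word_proportion	voiced_consonant	proportion	en,nl,de,zh
onset_nasal_count	onset	manner=nasal	count	en,nl,de,zh
onset_plosive_count	onset	manner=plosive	count	en,nl,de,zh
onset_fricative_count	onset	manner=fricative	count	en,nl,de,zh
onset_affricate_count	onset	manner=affricate	count	en,nl,de,zh
onset_approximant_count	onset	manner=approximant	count	en,nl,de,zh
onset_lateral_count	onset	manner=lateral	count	en,nl,de,zh
onset_trill_count	onset	manner=trill	count	nl,de
onset_bilabial_count	onset	place=bilabial	count	en,nl,de,zh
onset_labiodental_count	onset	place=labiodental	count	en,nl,de,zh
onset_dental_count	onset	place=dental	count	en
onset_alveolar_count	onset	place=alveolar	count	en,nl,de,zh
onset_postalveolar_count	onset	place=postalveolar	count	en,nl,de,zh
onset_palatal_count	onset	place=palatal	count	en,nl,de,zh
onset_velar_count	onset	place=velar	count	en,nl,de,zh
onset_uvular_count	onset	place=uvular	count	nl,de
onset_glottal_count	onset	place=glottal	count	en,nl,de,zh
onset_voiced_count	onset	voiced_consonant	count	en,nl,de,zh
nasal_first	first_consonant	manner=nasal	indicator	en,nl,de,zh
plosive_first	first_consonant	manner=plosive	indicator	en,nl,de,zh
fricative_first	first_consonant	manner=fricative	indicator	en,nl,de,zh
affricate_first	first_consonant	manner=affricate	indicator	en,nl,de,zh
approximant_first	first_consonant	manner=approximant	indicator	en,nl,de,zh
lateral_first	first_consonant	manner=lateral	indicator	en,nl,de,zh
trill_first	first_consonant	manner=trill	indicator	nl,de
bilabial_first	first_consonant	place=bilabial	indicator	en,nl,de,zh
labiodental_first	first_consonant	place=labiodental	indicator	en,nl,de,zh
dental_first	first_consonant	place=dental	indicator	en
alveolar_first	first_consonant	place=alveolar	indicator	en,nl,de,zh
postalveolar_first	first_consonant	place=postalveolar	indicator	en,nl,de,zh
palatal_first	first_consonant	place=palatal	indicator	en,nl,de,zh
velar_first	first_consonant	place=velar	indicator	en,nl,de,zh
uvular_first	first_consonant	place=uvular	indicator	nl,de
glottal_first	first_consonant	place=glottal	indicator	en,nl,de,zh
voiced_first	first_consonant	voiced_consonant	indicator	en,nl,de,zh
phoneme_count	word_count	any	count	en,nl,de,zh
syllable_count	word_count	syllable	count	en,nl,de,zh
vowel_count	word_count	sound_class=vowel	count	en,nl,de,zh
consonant_count	word_count	sound_class=consonant	count	en,nl,de,zh
vowel_proportion	word_proportion	sound_class=vowel	proportion	en,nl,de,zh
consonant_proportion	word_proportion	sound_class=consonant	proportion	en,nl,de,zh
long_vowel_count	word_count	vowel_long	count	en,nl,de,zh
long_vowel_proportion	word_proportion	vowel_long	proportion	en,nl,de,zh
diphthong_count	word_count	vowel_diphthong	count	en,nl,de,zh
diphthong_proportion	word_proportion	vowel_diphthong	proportion	en,nl,de,zh
rounded_vowel_count	word_count	vowel_rounded	count	en,nl,de,zh
rounded_vowel_proportion	word_proportion	vowel_rounded	proportion	en,nl,de,zh
front_vowel_count	word_count	backness=front	count	en,nl,de,zh
front_vowel_proportion	word_proportion	backness=front	proportion	en,nl,de,zh
back_vowel_count	word_count	backness=back	count	en,nl,de,zh
back_vowel_proportion	word_proportion	backness=back	proportion	en,nl,de,zh
first_vowel_height_close	vowel	height=close	indicator	en,nl,de,zh
first_vowel_height_near_close	vowel	height=near-close	indicator	en,nl,de,zh
first_vowel_height_close_mid	vowel	height=close-mid	indicator	en,nl,de
first_vowel_height_mid	vowel	height=mid	indicator	en,nl,de,zh
first_vowel_height_open_mid	vowel	height=open-mid	indicator	en,nl,de
first_vowel_height_near_open	vowel	height=near-open	indicator	en,nl,de,zh
first_vowel_height_open	vowel	height=open	indicator	en,nl,de,zh
first_vowel_backness_front	vowel	backness=front	indicator	en,nl,de,zh
first_vowel_backness_near_front	vowel	backness=near-front	indicator	en,nl,de
first_vowel_backness_central	vowel	backness=central	indicator	en,nl,de,zh
first_vowel_backness_near_back	vowel	backness=near-back	indicator	en,nl,de
first_vowel_backness_back	vowel	backness=back	indicator	en,nl,de,zh
first_vowel_rounded	vowel	vowel_rounded	indicator	en,nl,de,zh
first_vowel_long	vowel	vowel_long	indicator	en,nl,de,zh
first_vowel_diphthong	vowel	vowel_diphthong	indicator	en,nl,de,zh
tone_1_first	vowel	tone=1	indicator	zh
tone_2_first	vowel	tone=2	indicator	zh
tone_3_first	vowel	tone=3	indicator	zh
tone_4_first	vowel	tone=4	indicator	zh
tone_5_first	vowel	tone=5	indicator	zh
tone_mean	vowel	tone_mean	level	zh
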