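symbol	sound_class	manner	place	voiced	height	backness	rounded	long	diphthong
p	consonant	plosive	bilabial	false	none	none	false	false	false
b	consonant	plosive	bilabial	true	none	none	false	false	false
t	consonant	plosive	alveolar	false	none	none	false	false	false
d	consonant	plosive	alveolar	true	none	none	false	false	false
k	consonant	plosive	velar	false	none	none	false	false	false
g	consonant	plosive	velar	true	none	none	false	false	false
m	consonant	nasal	bilabial	true	none	none	false	false	false
n	consonant	nasal	alveolar	true	none	none	false	false	false
N	consonant	nasal	velar	true	none	none	false	false	false
f	consonant	fricative	labiodental	false	none	none	false	false	false
v	consonant	fricative	labiodental	true	none	none	false	false	false
s	consonant	fricative	alveolar	false	none	none	false	false	false
z	consonant	fricative	alveolar	true	none	none	false	false	false
S	consonant	fricative	postalveolar	false	none	none	false	false	false
Z	consonant	fricative	postalveolar	true	none	none	false	false	false
C	consonant	fricative	palatal	false	none	none	false	false	false
x	consonant	fricative	velar	false	none	none	false	false	false
h	consonant	fricative	glottal	false	none	none	false	false	false
pf	consonant	affricate	labiodental	false	none	none	false	false	false
ts	consonant	affricate	alveolar	false	none	none	false	false	false
tS	consonant	affricate	postalveolar	false	none	none	false	false	false
r	consonant	trill	alveolar	true	none	none	false	false	false
R	consonant	fricative	uvular	true	none	none	false	false	false
l	consonant	lateral	alveolar	true	none	none	false	false	false
j	consonant	approximant	palatal	true	none	none	false	false	false
i	vowel	none	none	true	close	front	false	true	false
I	vowel	none	none	true	near-close	near-front	false	false	false
y	vowel	none	none	true	close	front	true	true	false
Y	vowel	none	none	true	near-close	near-front	true	false	false
u	vowel	none	none	true	close	back	true	true	false
U	vowel	none	none	true	near-close	near-back	true	false	false
e	vowel	none	none	true	close-mid	front	false	true	false
2	vowel	none	none	true	close-mid	front	true	true	false
o	vowel	none	none	true	close-mid	back	true	true	false
E	vowel	none	none	true	open-mid	front	false	false	false
9	vowel	none	none	true	open-mid	front	true	false	false
O	vowel	none	none	true	open-mid	back	true	false	false
a	vowel	none	none	true	open	front	false	false	false
@	vowel	none	none	true	mid	central	false	false	false
aI	vowel	none	none	true	open	front	false	false	true
aU	vowel	none	none	true	open	back	false	false	true
OY	vowel	none	none	true	open-mid	back	true	false	true
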