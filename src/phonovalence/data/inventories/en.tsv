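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
T	consonant	fricative	dental	false	none	none	false	false	false
D	consonant	fricative	dental	true	none	none	false	false	false
s	consonant	fricative	alveolar	false	none	none	false	false	false
z	consonant	fricative	alveolar	true	none	none	false	false	false
S	consonant	fricative	postalveolar	false	none	none	false	false	false
Z	consonant	fricative	postalveolar	true	none	none	false	false	false
h	consonant	fricative	glottal	false	none	none	false	false	false
tS	consonant	affricate	postalveolar	false	none	none	false	false	false
dZ	consonant	affricate	postalveolar	true	none	none	false	false	false
r	consonant	approximant	postalveolar	true	none	none	false	false	false
l	consonant	lateral	alveolar	true	none	none	false	false	false
w	consonant	approximant	bilabial	true	none	none	true	false	false
j	consonant	approximant	palatal	true	none	none	false	false	false
i	vowel	none	none	true	close	front	false	true	false
I	vowel	none	none	true	near-close	near-front	false	false	false
e	vowel	none	none	true	close-mid	front	false	false	false
E	vowel	none	none	true	open-mid	front	false	false	false
ae	vowel	none	none	true	near-open	front	false	false	false
a	vowel	none	none	true	open	front	false	false	false
A	vowel	none	none	true	open	back	false	true	false
V	vowel	none	none	true	open-mid	back	false	false	false
O	vowel	none	none	true	open-mid	back	true	true	false
o	vowel	none	none	true	close-mid	back	true	false	false
U	vowel	none	none	true	near-close	near-back	true	false	false
u	vowel	none	none	true	close	back	true	true	false
@	vowel	none	none	true	mid	central	false	false	false
aI	vowel	none	none	true	open	front	false	false	true
aU	vowel	none	none	true	open	back	false	false	true
OI	vowel	none	none	true	open-mid	back	true	false	true
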