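symbol	sound_class	manner	place	voiced	height	backness	rounded	long	diphthong
b	consonant	plosive	bilabial	false	none	none	false	false	false
p	consonant	plosive	bilabial	false	none	none	false	false	false
m	consonant	nasal	bilabial	true	none	none	false	false	false
f	consonant	fricative	labiodental	false	none	none	false	false	false
d	consonant	plosive	alveolar	false	none	none	false	false	false
t	consonant	plosive	alveolar	false	none	none	false	false	false
n	consonant	nasal	alveolar	true	none	none	false	false	false
l	consonant	lateral	alveolar	true	none	none	false	false	false
g	consonant	plosive	velar	false	none	none	false	false	false
k	consonant	plosive	velar	false	none	none	false	false	false
h	consonant	fricative	velar	false	none	none	false	false	false
j	consonant	affricate	palatal	false	none	none	false	false	false
q	consonant	affricate	palatal	false	none	none	false	false	false
x	consonant	fricative	palatal	false	none	none	false	false	false
zh	consonant	affricate	postalveolar	false	none	none	false	false	false
ch	consonant	affricate	postalveolar	false	none	none	false	false	false
sh	consonant	fricative	postalveolar	false	none	none	false	false	false
r	consonant	approximant	postalveolar	true	none	none	false	false	false
z	consonant	affricate	alveolar	false	none	none	false	false	false
c	consonant	affricate	alveolar	false	none	none	false	false	false
s	consonant	fricative	alveolar	false	none	none	false	false	false
y	consonant	approximant	palatal	true	none	none	false	false	false
w	consonant	approximant	bilabial	true	none	none	true	false	false
ng	consonant	nasal	velar	true	none	none	false	false	false
a	vowel	none	none	true	open	central	false	false	false
o	vowel	none	none	true	mid	back	true	false	false
e	vowel	none	none	true	mid	back	false	false	false
i	vowel	none	none	true	close	front	false	false	false
u	vowel	none	none	true	close	back	true	false	false
v	vowel	none	none	true	close	front	true	false	false
er	vowel	none	none	true	mid	central	false	false	false
ai	vowel	none	none	true	open	front	false	false	true
ei	vowel	none	none	true	mid	front	false	false	true
ao	vowel	none	none	true	open	back	false	false	true
ou	vowel	none	none	true	mid	back	true	false	true
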