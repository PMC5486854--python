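final	phonemes
a	a
o	o
e	e
i	i
u	u
v	v
er	er
ai	ai
ei	ei
ao	ao
ou	ou
an	a n
en	e n
ang	a ng
eng	e ng
ong	o ng
ia	i a
ie	i e
iao	i ao
iu	i ou
ian	i a n
in	i n
iang	i a ng
ing	i ng
iong	i o ng
ua	u a
uo	u o
uai	u ai
ui	u ei
uan	u a n
un	u n
uang	u a ng
ueng	u e ng
ue	v e
ve	v e
van	v a n
vn	v n
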