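# Legal word/syllable onsets for German.
p
b
t
d
k
g
m
n
f
v
s
z
S
h
pf
ts
tS
r
R
l
j
p l
p r
b l
b r
t r
d r
k l
k r
k n
g l
g r
g n
f l
f r
S l
S m
S n
S p
S t
S r
S v
ts v
pf l
pf r
S p r
S t r
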