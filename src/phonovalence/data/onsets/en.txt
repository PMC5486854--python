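# Legal word/syllable onsets for English (one onset per line, symbols
# space-separated). Single consonants first, then clusters.
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
T
D
s
z
S
h
tS
dZ
r
l
w
j
p l
p r
b l
b r
t r
d r
t w
k l
k r
k w
g l
g r
f l
f r
T r
S r
s l
s m
s n
s p
s t
s k
s w
s p l
s p r
s t r
s k r
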