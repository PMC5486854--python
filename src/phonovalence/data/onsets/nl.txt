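# Legal word/syllable onsets for Dutch.
p
b
t
d
k
m
n
f
v
s
z
S
x
X
h
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
k n
k w
f l
f r
v l
v r
s l
s m
s n
s p
s t
s x
z w
X r
s p r
s t r
s x r
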