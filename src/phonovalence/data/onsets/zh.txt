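# Legal syllable onsets for Mandarin (single initials only; Mandarin has
# no onset clusters).
b
p
m
f
d
t
n
l
g
k
h
j
q
x
zh
ch
sh
r
z
c
s
y
w
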