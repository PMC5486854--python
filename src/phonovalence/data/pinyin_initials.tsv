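initial	phonemes
b	b
p	p
m	m
f	f
d	d
t	t
n	n
l	l
g	g
k	k
h	h
j	j
q	q
x	x
zh	zh
ch	ch
sh	sh
r	r
z	z
c	c
s	s
y	y
w	w
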