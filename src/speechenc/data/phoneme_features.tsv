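phoneme	dorsal	coronal	labial	plosive	fricative	nasal	voiced	high	mid	low	front	back	vowel
aa	0	0	0	0	0	0	0	0	0	1	0	1	1
ae	0	0	0	0	0	0	0	0	0	1	1	0	1
ah	0	0	0	0	0	0	0	0	1	0	0	0	1
ao	0	0	0	0	0	0	0	0	0	1	0	1	1
aw	0	0	0	0	0	0	0	0	0	1	0	1	1
ay	0	0	0	0	0	0	0	0	0	1	1	0	1
eh	0	0	0	0	0	0	0	0	1	0	1	0	1
er	0	0	0	0	0	0	0	0	1	0	0	0	1
ey	0	0	0	0	0	0	0	0	1	0	1	0	1
ih	0	0	0	0	0	0	0	1	0	0	1	0	1
iy	0	0	0	0	0	0	0	1	0	0	1	0	1
ow	0	0	0	0	0	0	0	0	1	0	0	1	1
oy	0	0	0	0	0	0	0	0	1	0	0	1	1
uh	0	0	0	0	0	0	0	1	0	0	0	1	1
uw	0	0	0	0	0	0	0	1	0	0	0	1	1
b	0	0	1	1	0	0	1	0	0	0	0	0	0
d	0	1	0	1	0	0	1	0	0	0	0	0	0
g	1	0	0	1	0	0	1	0	0	0	0	0	0
p	0	0	1	1	0	0	0	0	0	0	0	0	0
t	0	1	0	1	0	0	0	0	0	0	0	0	0
k	1	0	0	1	0	0	0	0	0	0	0	0	0
ch	0	1	0	1	1	0	0	0	0	0	0	0	0
jh	0	1	0	1	1	0	1	0	0	0	0	0	0
f	0	0	1	0	1	0	0	0	0	0	0	0	0
v	0	0	1	0	1	0	1	0	0	0	0	0	0
th	0	1	0	0	1	0	0	0	0	0	0	0	0
dh	0	1	0	0	1	0	1	0	0	0	0	0	0
s	0	1	0	0	1	0	0	0	0	0	0	0	0
z	0	1	0	0	1	0	1	0	0	0	0	0	0
sh	0	1	0	0	1	0	0	0	0	0	0	0	0
zh	0	1	0	0	1	0	1	0	0	0	0	0	0
hh	1	0	0	0	1	0	0	0	0	0	0	0	0
m	0	0	1	0	0	1	1	0	0	0	0	0	0
n	0	1	0	0	0	1	1	0	0	0	0	0	0
ng	1	0	0	0	0	1	1	0	0	0	0	0	0
l	0	1	0	0	0	0	1	0	0	0	0	0	0
r	0	1	0	0	0	0	1	0	0	0	0	0	0
w	1	0	1	0	0	0	1	0	0	0	0	0	0
y	1	0	0	0	0	0	1	0	0	0	0	0	0
sil	0	0	0	0	0	0	0	0	0	0	0	0	0
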