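symbol	bases
A	A
C	C
G	G
T	T
R	AG
Y	CT
S	CG
W	AT
K	GT
M	AC
B	CGT
D	AGT
H	ACT
V	ACG
N	ACGT
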