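	A	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	9	0	0	0	6	0	0	0	0	0	0	0	0	0	0	0	0	0	0
D	0	9	6	0	0	0	0	0	0	0	3	0	3	0	3	3	0	0	0
E	0	6	9	0	0	0	0	0	0	0	3	0	3	0	3	3	0	0	0
F	0	0	0	9	0	0	3	0	3	3	0	0	0	0	0	0	3	6	6
G	6	0	0	0	9	0	0	0	0	0	0	0	0	0	0	0	0	0	0
H	0	0	0	0	0	9	0	6	0	0	3	0	3	6	3	3	0	0	0
I	0	0	0	3	0	0	9	0	6	6	0	0	0	0	0	0	6	3	3
K	0	0	0	0	0	6	0	9	0	0	3	0	3	6	3	3	0	0	0
L	0	0	0	3	0	0	6	0	9	6	0	0	0	0	0	0	6	3	3
M	0	0	0	3	0	0	6	0	6	9	0	0	0	0	0	0	6	3	3
N	0	3	3	0	0	3	0	3	0	0	9	0	6	3	6	6	0	0	0
P	0	0	0	0	0	0	0	0	0	0	0	9	0	0	0	0	0	0	0
Q	0	3	3	0	0	3	0	3	0	0	6	0	9	3	6	6	0	0	0
R	0	0	0	0	0	6	0	6	0	0	3	0	3	9	3	3	0	0	0
S	0	3	3	0	0	3	0	3	0	0	6	0	6	3	9	6	0	0	0
T	0	3	3	0	0	3	0	3	0	0	6	0	6	3	6	9	0	0	0
V	0	0	0	3	0	0	6	0	6	6	0	0	0	0	0	0	9	3	3
W	0	0	0	6	0	0	3	0	3	3	0	0	0	0	0	0	3	9	6
Y	0	0	0	6	0	0	3	0	3	3	0	0	0	0	0	0	3	6	9
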