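aa	hydrophobic	polar	charged	positive	negative	small	tiny	aromatic	aliphatic	proline
A	1	0	0	0	0	1	1	0	0	0
R	0	1	1	1	0	0	0	0	0	0
N	0	1	0	0	0	1	0	0	0	0
D	0	1	1	0	1	1	0	0	0	0
C	1	0	0	0	0	1	0	0	0	0
Q	0	1	0	0	0	0	0	0	0	0
E	0	1	1	0	1	0	0	0	0	0
G	1	0	0	0	0	1	1	0	0	0
H	1	1	1	1	0	0	0	1	0	0
I	1	0	0	0	0	0	0	0	1	0
L	1	0	0	0	0	0	0	0	1	0
K	1	1	1	1	0	0	0	0	0	0
M	1	0	0	0	0	0	0	0	0	0
F	1	0	0	0	0	0	0	1	0	0
P	0	0	0	0	0	1	0	0	0	1
S	0	1	0	0	0	1	1	0	0	0
T	1	1	0	0	0	1	0	0	0	0
W	1	1	0	0	0	0	0	1	0	0
Y	1	1	0	0	0	0	0	1	0	0
V	1	0	0	0	0	1	0	0	1	0
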