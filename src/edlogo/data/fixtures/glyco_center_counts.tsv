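symbol	0
A	0
C	0
D	0
E	0
F	0
G	0
H	0
I	0
K	0
L	0
M	0
N	5422
P	0
Q	0
R	0
S	0
T	0
V	0
W	0
Y	0
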