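# Generic amino-acid composition used as a SYNTHETIC stand-in background
# (the real glycosylation background table is not reproducible from printed text).
symbol	q
A	0.08259084993492839
C	0.013715086595254777
D	0.05456001601761937
E	0.06757433176494142
F	0.038642506757433165
G	0.07077785564120531
H	0.022724997497246966
I	0.05966563219541494
K	0.05846431074181598
L	0.09670637701471615
M	0.024226649314245664
N	0.04064470918009809
P	0.04705175693262588
Q	0.03934327760536589
R	0.05536089698668534
S	0.06567223946340973
T	0.053458804685153655
V	0.06877565321854037
W	0.010811893082390627
Y	0.02923215537090799
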