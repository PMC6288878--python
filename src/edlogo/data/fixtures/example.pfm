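>EX0001 example-motif
A [ 10  2  0  0  8  1 ]
C [  1  1 12  9  0  2 ]
G [  1  8  0  2  1  9 ]
T [  0  1  0  1  3  0 ]
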