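symbol	1
A	0.33
C	0.33
G	0.33
T	0.01
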