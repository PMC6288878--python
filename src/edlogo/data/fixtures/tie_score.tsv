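# mode = raw
# centering = none
symbol	1
w	0
x	0
y	1
z	1
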