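# SYNTHETIC transcription-factor-style count matrix (G/C depleted mid-site).
symbol	1	2	3	4	5	6
A	300	50	50	100	450	400
C	200	100	850	800	30	50
G	300	50	50	40	30	500
T	200	800	50	60	490	50
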