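# Signature-12-style fixture: center mutation-type frequencies as printed;
# flanking base frequencies are SYNTHETIC stand-ins (G depleted at +1).
symbol	-2	-1	0	1	2
A	0.28	0.3		0.35	0.27
C	0.22	0.25		0.33	0.24
G	0.25	0.2		0.02	0.24
T	0.25	0.25		0.3	0.25
C→A			0.0025		
C→G			0.0025		
C→T			0.96		
T→A			0.0025		
T→C			0.03		
T→G			0.0025		
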