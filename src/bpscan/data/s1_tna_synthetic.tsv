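	pos1	pos2	pos3	pos4	pos5	pos6	pos7
A	0.05	0.85	0.05	0.00	0.85	1.00	0.05
C	0.05	0.05	0.85	0.00	0.05	0.00	0.85
G	0.05	0.05	0.05	0.00	0.05	0.00	0.05
T	0.85	0.05	0.05	1.00	0.05	0.00	0.05
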