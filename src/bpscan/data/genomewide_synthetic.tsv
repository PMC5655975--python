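	pos1	pos2	pos3	pos4	pos5	pos6	pos7
A	0.22	0.24	0.15	0.10	0.24	0.85	0.15
C	0.28	0.26	0.30	0.10	0.26	0.05	0.35
G	0.22	0.24	0.15	0.05	0.24	0.05	0.15
T	0.28	0.26	0.40	0.75	0.26	0.05	0.35
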