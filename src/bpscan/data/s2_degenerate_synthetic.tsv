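	pos1	pos2	pos3	pos4	pos5	pos6	pos7
A	0.25	0.25	0.20	0.15	0.25	0.70	0.20
C	0.25	0.25	0.30	0.15	0.25	0.10	0.30
G	0.25	0.25	0.15	0.10	0.25	0.10	0.15
T	0.25	0.25	0.35	0.60	0.25	0.10	0.35
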