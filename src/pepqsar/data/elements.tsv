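element	vdw_radius	lj_epsilon
H	1.20	0.016
C	1.70	0.107
N	1.55	0.095
O	1.52	0.116
F	1.47	0.061
P	1.80	0.200
S	1.80	0.250
Cl	1.75	0.265
Br	1.85	0.320
I	1.98	0.400
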