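gene	A_TL_r1	A_TL_r2	B_TL_r1	B_TL_r2
g1	0.001	0.002	0.001	0.001
g2	0.010	0.015	0.001	0.005
g3	0.001	0.001	0.900	0.850
g4	0.001	0.001	0.001	0.001
g5	0.019	0.001	0.020	0.001
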