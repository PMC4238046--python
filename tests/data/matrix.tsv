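# 5-gene translatome fixture, log10 intensities
gene	A_TL_r1	A_TL_r2	B_TL_r1	B_TL_r2
g1	2.10	2.00	2.90	2.95
g2	3.00	3.10	3.02	3.08
g3	1.50	1.55	1.00	0.95
g4	2.50	2.45	2.52	2.48
g5	3.50	3.55	3.20	3.25
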