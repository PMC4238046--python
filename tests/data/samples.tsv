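sample	group	compartment	replicate
A_TL_r1	A	TL	1
A_TL_r2	A	TL	2
B_TL_r1	B	TL	1
B_TL_r2	B	TL	2
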