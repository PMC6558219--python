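comparison	mode	n_a	n_b	n_common	pct_printed	method
fig2c	GAS	6	17	3	13.0	sum
fig2c	ISRE	81	45	37	29.4	sum
fig2c	NFKB	85	28	18	15.9	sum
fig2c	GAS-ISRE	51	53	34	32.7	sum
fig2c	GAS-NFKB	23	40	7	11.1	sum
fig2c	ISRE-NFKB	94	59	33	21.6	sum
fig2c	GAS-ISRE-NFKB	99	178	82	29.6	sum
fig1d	common_up	579	536	436	64.21	jaccard
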