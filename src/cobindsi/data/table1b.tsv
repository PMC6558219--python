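gene	fc_ifn	fc_lps	fc_combo	gas	isre	nfkb	si_marked
Cxcl9	82.2	4.0	2380.5	1	0	1	1
F830016B08Rik	1272.1	6.4	2306.6	1	1	1	1
Gm4841	1087.3	9.0	1650.3	1	1	1	1
Nos2	1.8	90.9	933.3	1	1	1	1
BC023105	600.8	19.9	909.4	0	0	0	1
Gbp4	304.3	16.4	795.8	1	1	1	1
Iigp1	687.7	9.2	779.3	1	1	0	1
Ubd	95.6	5.8	655.1	1	1	1	1
Gbp10	315.9	21.1	588.2	1	1	1	1
Gbp9	304.8	22.9	586.1	0	1	1	1
Gbp6	266.1	23.5	555.3	1	1	1	1
Serpina3f	200.1	13.0	529.6	1	1	1	1
Gbp11	302.3	13.6	482.7	1	1	0	1
Gm12250	502.9	3.6	477.8	1	1	0	0
Gbp8	215.5	12.9	405.2	1	1	1	1
Ciita	704.4	2.0	376.5	1	1	1	0
Cxcl10	49.8	4.6	364.9	1	1	1	1
Gbp1	295.0	17.5	364.8	0	1	0	1
Gja4	82.3	1.6	329.9	1	1	1	1
Gm4951	300.1	6.9	327.2	1	0	0	1
Batf2	191.4	3.1	298.4	1	1	0	1
Lcn2	3.8	36.5	289.2	0	0	1	1
Gbp2	219.7	13.4	284.4	0	1	1	1
Igtp	328.8	5.3	274.1	1	1	0	0
Tgtp2	261.9	2.6	262.5	1	1	0	0
Gm5970	183.1	2.3	236.1	0	0	0	1
Ccl8	115.8	18.6	231.4	1	1	1	1
Tgtp1	216.7	2.4	222.4	1	1	1	1
Gbp5	67.7	9.2	211.5	1	1	1	1
Saa3	4.2	66.6	196.1	1	0	1	1
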