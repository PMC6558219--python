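gene	fc_ifn	fc_lps	fc_combo	gas	isre	nfkb	si_marked
F830016B08Rik	196.8	6.4	345.9	1	1	0	1
Ifi44	356.3	4.4	343.7	0	1	0	0
Cxcl10	75.9	4.6	312.1	1	1	1	1
BC023105	187.1	19.9	289.2	0	0	0	1
Nos2	4.9	90.9	287.1	1	1	1	1
Gm4955	209.5	5.4	260.2	0	0	0	1
Gm15725	294.6	2.9	259.8	0	0	0	0
Iigp1	179.7	9.2	242.3	1	1	0	1
Gm4951	178.6	6.9	233.4	1	1	0	1
Gbp9	78.8	22.9	215.9	0	1	1	1
Gbp11	62.1	13.6	196.5	1	1	0	1
Apod	213.7	2.2	194.9	0	1	1	0
Gm4841	99.8	9.0	181.4	1	1	0	1
Gbp4	36.4	16.4	162.0	1	1	1	1
Gm14446	164.5	1.8	157.8	0	0	0	0
Mx1	128.8	3.3	155.9	0	1	1	1
Ifit1	113.3	11.1	153.6	0	1	0	1
Gm12250	94.8	3.6	142.3	1	1	0	1
Gm4902	126.5	3.8	139.3	0	0	0	1
Tnfsf10	35.8	3.2	128.9	1	1	1	1
Usp18	96.3	8.9	127.5	0	1	1	1
Gbp1	91.7	17.5	125.5	0	1	0	1
Gbp6	36.9	23.5	117.2	1	1	1	1
Gbp10	35.6	21.1	115.2	0	1	1	1
Ch25h	3.5	19.6	112.6	1	1	1	1
Tgtp2	114.2	2.6	110.7	1	1	0	0
Gm6904	94.9	2.6	107.8	0	1	0	1
Zbp1	95.5	5.8	106.3	1	1	1	1
Saa3	5.1	66.6	105.7	1	0	1	1
Phf11	100.2	3.2	105.7	0	0	0	1
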