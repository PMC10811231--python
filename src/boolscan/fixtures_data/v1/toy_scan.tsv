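# model	toy_macrophage_m1
# model_hash	893c266bae60cdbc
# fixed	
# free	GF,IFNG,IL10,LPS,TNFa
combination_index	status	GF	IFNG	IL10	LPS	TNFa	TLR4	TNFR	IFNGR	GFR	IL10R	NFkB	JAK1	JAK2	STAT1	ERK	MYC	STAT3	BCL2	CASP3	Apoptosis_M1_macrophage	Proliferation_M1_macrophage	TNF_release_signal	Inflammation_signal
0	stable	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0
1	stable	1	0	0	0	0	0	0	0	1	0	0	0	0	0	1	1	0	0	1	1	0	0	0
2	stable	0	1	0	0	0	0	0	1	0	0	0	1	1	1	0	0	0	0	1	1	0	1	1
3	stable	1	1	0	0	0	0	0	1	1	0	0	1	1	1	1	1	0	0	1	1	0	1	1
4	stable	0	0	1	0	0	0	0	0	0	1	0	0	0	0	0	0	1	0	1	1	0	0	0
5	stable	1	0	1	0	0	0	0	0	1	1	0	0	0	0	1	1	1	0	1	1	0	0	0
6	stable	0	1	1	0	0	0	0	1	0	1	0	1	1	1	0	0	1	0	1	1	0	1	1
7	stable	1	1	1	0	0	0	0	1	1	1	0	1	1	1	1	1	1	0	1	1	0	1	1
8	stable	0	0	0	1	0	1	0	0	0	0	1	0	0	0	0	0	0	1	0	0	0	0	1
9	stable	1	0	0	1	0	1	0	0	1	0	1	0	0	0	1	1	0	1	0	0	1	0	1
10	stable	0	1	0	1	0	1	0	1	0	0	1	1	1	1	0	0	0	1	0	0	0	1	1
11	stable	1	1	0	1	0	1	0	1	1	0	1	1	1	1	1	1	0	1	0	0	1	1	1
12	stable	0	0	1	1	0	1	0	0	0	1	1	0	0	0	0	0	1	1	0	0	0	0	1
13	stable	1	0	1	1	0	1	0	0	1	1	1	0	0	0	1	1	1	1	0	0	0	0	1
14	stable	0	1	1	1	0	1	0	1	0	1	1	1	1	1	0	0	1	1	0	0	0	1	1
15	stable	1	1	1	1	0	1	0	1	1	1	1	1	1	1	1	1	1	1	0	0	0	1	1
16	stable	0	0	0	0	1	0	1	0	0	0	1	0	0	0	0	0	0	1	0	0	0	0	1
17	stable	1	0	0	0	1	0	1	0	1	0	1	0	0	0	1	1	0	1	0	0	1	0	1
18	stable	0	1	0	0	1	0	1	1	0	0	1	1	1	1	0	0	0	1	0	0	0	1	1
19	stable	1	1	0	0	1	0	1	1	1	0	1	1	1	1	1	1	0	1	0	0	1	1	1
20	stable	0	0	1	0	1	0	1	0	0	1	1	0	0	0	0	0	1	1	0	0	0	0	1
21	stable	1	0	1	0	1	0	1	0	1	1	1	0	0	0	1	1	1	1	0	0	0	0	1
22	stable	0	1	1	0	1	0	1	1	0	1	1	1	1	1	0	0	1	1	0	0	0	1	1
23	stable	1	1	1	0	1	0	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	1	1
24	stable	0	0	0	1	1	1	1	0	0	0	1	0	0	0	0	0	0	1	0	0	0	0	1
25	stable	1	0	0	1	1	1	1	0	1	0	1	0	0	0	1	1	0	1	0	0	1	0	1
26	stable	0	1	0	1	1	1	1	1	0	0	1	1	1	1	0	0	0	1	0	0	0	1	1
27	stable	1	1	0	1	1	1	1	1	1	0	1	1	1	1	1	1	0	1	0	0	1	1	1
28	stable	0	0	1	1	1	1	1	0	0	1	1	0	0	0	0	0	1	1	0	0	0	0	1
29	stable	1	0	1	1	1	1	1	0	1	1	1	0	0	0	1	1	1	1	0	0	0	0	1
30	stable	0	1	1	1	1	1	1	1	0	1	1	1	1	1	0	0	1	1	0	0	0	1	1
31	stable	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	1	1
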