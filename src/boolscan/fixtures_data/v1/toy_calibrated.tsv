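node	mean	fixed_flag
GF	1	1
IFNG	1	1
IL10	0	1
LPS	0.5	0
TNFa	1	1
TLR4	0.5	0
TNFR	1	1
IFNGR	1	1
GFR	1	1
IL10R	0	1
NFkB	1	1
JAK1	1	1
JAK2	1	1
STAT1	1	1
ERK	1	1
MYC	1	1
STAT3	0	1
BCL2	1	1
CASP3	0	1
Apoptosis_M1_macrophage	0	1
Proliferation_M1_macrophage	1	1
TNF_release_signal	1	1
Inflammation_signal	1	1
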