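node	value	provenance
NFkB	1	literature
TNFR	1	expression
STAT1	1	literature
MYC	1	expression
CASP3	0	expression
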