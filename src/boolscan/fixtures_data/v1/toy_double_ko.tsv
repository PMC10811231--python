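target	status	Apoptosis_M1_macrophage	Proliferation_M1_macrophage	TNF_release_signal	Inflammation_signal	synergy
BCL2+ERK	steady	induced	suppressed	unchanged	unchanged	0
BCL2+JAK1	steady	induced	unchanged	unchanged	unchanged	0
BCL2+JAK2	steady	induced	unchanged	unchanged	unchanged	0
BCL2+NFkB	steady	induced	suppressed	unchanged	unchanged	0
ERK+JAK1	steady	unchanged	suppressed	unchanged	unchanged	0
ERK+JAK2	steady	unchanged	suppressed	unchanged	unchanged	0
ERK+NFkB	steady	induced	suppressed	unchanged	unchanged	0
JAK1+JAK2	steady	unchanged	unchanged	suppressed	unchanged	1
JAK1+NFkB	steady	induced	suppressed	unchanged	unchanged	0
JAK2+NFkB	steady	induced	suppressed	unchanged	unchanged	0
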