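target	status	Apoptosis_M1_macrophage	Proliferation_M1_macrophage	TNF_release_signal	Inflammation_signal
NFkB	steady	induced	suppressed	unchanged	unchanged
JAK1	steady	unchanged	unchanged	unchanged	unchanged
JAK2	steady	unchanged	unchanged	unchanged	unchanged
ERK	steady	unchanged	suppressed	unchanged	unchanged
BCL2	steady	induced	unchanged	unchanged	unchanged
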