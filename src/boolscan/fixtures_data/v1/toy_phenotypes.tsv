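node	required_value
Apoptosis_M1_macrophage	0
Proliferation_M1_macrophage	1
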