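side	Normal	Hypoplasia	Absence
L	2073	71	102
R	2025	106	115
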