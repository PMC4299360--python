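side	Normal	Mild variation	Hypoplasia	Absence
L	2041	135	56	14
R	1817	198	150	81
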