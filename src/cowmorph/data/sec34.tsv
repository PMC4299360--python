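a1_status	FTP	no FTP
Normal	295	1317
Mild variation	70	263
Hypoplasia	41	165
Absence	32	63
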