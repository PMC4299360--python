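a1_status	Adult	FTP-I	FTP-II	FTP-III	FTP-IV
Normal	576	8	16	13	21
Mild variation	281	5	20	23	4
Hypoplasia	172	1	15	16	2
Absence	73	2	7	12	1
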