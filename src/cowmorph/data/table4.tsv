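acoa	Normal	Double-branch	Y pattern	Window pattern	Ampulla	Circle pattern	Absence	Not clear
Cases	1631	76	22	88	14	3	383	29
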