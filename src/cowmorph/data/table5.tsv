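posterior	a	b	c	d	e	f	g	h	i	j	k
Cases	230	27	104	1066	512	90	63	61	37	28	28
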