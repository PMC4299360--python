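anterior	a	b	c	d	e	f	g	h	i	j	k
I	143	16	44	593	287	47	31	34	17	8	17
II	27	3	17	160	70	12	10	11	6	2	7
III	16	0	9	109	40	10	8	5	1	2	3
IV	2	2	7	43	18	10	5	2	2	3	1
V1	42	6	27	159	93	9	7	9	11	12	0
V2	0	0	0	2	4	2	2	0	0	1	0
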