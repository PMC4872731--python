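sample	private_fusions	private_genes	private_readthrough	recurrent_fusions	recurrent_genes	recurrent_readthrough
01	10	18	3	15	29	11
02	22	41	11	19	37	14
03	30	41	7	38	64	19
04	63	88	17	46	77	23
05	30	39	7	39	57	15
07	22	37	9	29	48	15
08	24	32	4	43	63	14
09	14	27	5	26	49	20
10	13	20	3	27	43	11
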