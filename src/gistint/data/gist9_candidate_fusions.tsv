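sample	tools	gene5	chrom5	fold_change5	gene3	chrom3	fold_change3	read_through
01	DF,CS	POLA2	11		CDC42EP2	11		yes
01	DF	IGF2	11		ACTB	7		no
01	CS	STX16	20		NPEPL1	20	2.10	yes
02	DF,CS	POLA2	11		CDC42EP2	11		yes
02	DF	FBXO25	8		BET1L	11		no
03	DF	EPS15	1		OSBPL9	1		no
03	DF,CS	POLA2	11		CDC42EP2	11		yes
03	DF	IGF2	11		SEPT9	17		no
03	DF	GAPDH	12		IGF2	11		no
03	DF	C8orf42	8		FBXO25	8		yes
03	DF	IGF2	11		CCND1	11	2.77	no
03	CS	LYPLA1	8		TCEA1	8		no
03	CS	FXYD6-FXYD2	11		DSCAML1	11	2.00	yes
04	DF	IGF2	11	2.18	EPC1	10		no
04	DF	IGF2	11	2.18	SQSTM1	5		no
04	DF	IGF2	11	2.18	TOP2B	3		no
04	DF	IGF2	11	2.18	KIT	4	2.59	no
04	DF	HNRNPA2B1	7		PCBD2	5		no
04	DF	UBR4	1	3.36	IGF2	11	2.18	no
04	DF	C8orf42	8		FBXO25	8		yes
04	DF,CS	POLA2	11		CDC42EP2	11		yes
04	CS	FXYD6-FXYD2	11		DSCAML1	11	3.14	yes
05	DF	POLA2	11		CDC42EP2	11		yes
05	DF	IGF2	11		LASP1	17		no
05	DF	IGF2	11		FUS	16		no
05	CS	STX16	20		NPEPL1	20		yes
07	DF,CS	P2RY6	11	5.27	ARHGEF17	11		yes
07	CS	CTSL3	9	4.48	GABBR2	9		no
08	DF	IGF2	11		STAT5B	17		no
08	DF	HNRNPA2B1	7		PCBD2	5		no
08	DF	C8orf42	8		FBXO25	8		yes
08	DF	CTSL1	9		GAPDH	12		no
08	DF	IGF2	11		TNPO1	5		no
08	DF	KIT	4		IGF2	11		no
08	DF	KIT	4		PCBD2	5		no
08	CS	POLA2	11		CDC42EP2	11		yes
09	DF	C8orf42	8		FBXO25	8		yes
09	CS	POLA2	11		CDC42EP2	11		yes
09	CS	STX16	20		NPEPL1	20		yes
09	DF,CS	RALGPS1	9		LRSAM1	9		no
10	DF	IGF2	11		RBMS1	2		no
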