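ncbi_accession	gene	uniprot_accession	protein_name	mw_kda	pi	peptides_minus	coverage_minus	mascot_minus	peptides_plus	coverage_plus	mascot_plus
4506885	SEMG2	Q02383	semenogelin II precursor	65	9.0	9	20	1968	7	10	6998
38049014	SEMG1	P04279	semenogelin I isoform b preproprotein	45	9.2	6	14	1597	3	14	345
16933542	FN1	P02751	fibronectin 1 isoform 3 preproprotein	262	5.4	5	3	964
4502173	KLK3	Q546G3	prostate specific antigen isoform 1 preproprotein	29	7.6	6	38	486	3	15	255
42716297	CLU	P10909	clusterin isoform 1	58	6.2	2	3	233	4	12	203
4505185	MIF	P14174	macrophage migration inhibitory factor	12	7.7	2	9	206
4505821	PIP	P12273	prolactin-inducible protein precursor	16	8.2	3	48	123	5	44	11771
5031863	LGALS3BP	Q08380	galectin 3 binding protein	66	5.1	1	3	104
4502027	ALB	P02768	albumin preproprotein	71	5.9				7	17	1092
4503109	CST4	P01036	cystatin S precursor	16	4.9				2	32	188
71834855	KLK3	P07288	prostate specific antigen isoform 4 preproprotein	24	7.0				2	10	163
4502337	AZGP1	P25311	zinc alpha-2-glycoprotein 1	34	5.7	1	7	125	2	12	143
54607120	LTF	P02788	lactotransferrin precursor	80	8.5				1	3	140
6382064	ACPP	P15309	acid phosphatase, prostate short isoform precursor	45	5.8	3	8	220	3	8	316
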