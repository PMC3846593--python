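protein_name	gene	ncbi_accession	uniprot_accession	nsc_ratio	log2_nsc
fibronectin 1 isoform b precursor	FN1	16933542	P02751	ROS- only
macrophage migration inhibitory factor-1 peptide	MIF	4505185	P14174	ROS- only
galectin 3 binding protein	LGALS3BP	5031863	Q08380	ROS- only
cystatin S precursor	CST4	4503109	P01036	ROS+ only
albumin preprotein	ALB	4502027	P02768	ROS+ only
lactotransferrin precursor-1 peptide	LTF	54607120	P02788	ROS+ only
prostate specific antigen isoform 4 preprotein	KLK3	71834855	P07288	ROS+ only
prolactin induced protein	PIP	4505821	P12273	12.711	3.668
semenogelin II precursor	SEMG2	4506885	Q02383	1.338	0.420
acid phosphatase, prostate short isoform precursor	ACPP	6382064	P15309	1.063	0.088
clusterin preprotein	CLU	355594753	P10909	0.753	-0.409
zinc alpha-2-glycoprotein 1	AZGP1	4502337	P25311	0.354	-1.498
prostate specific antigen isoform 1 preprotein	KLK3	4502173	Q546G3	0.124	-3.012
semenogelin I isoform a preprotein	SEMG1	4506883	P04279	0.032	-4.966
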