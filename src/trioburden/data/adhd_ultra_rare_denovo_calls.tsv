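proband_id	gene	protein_change	chrom	pos	ref	alt	variant_class	mpc	pli	gnomad_nonneuro_af	ndd_risk
ADHD6.p1	RBBP6	p.Y170C	chr16	24567213	A	G	missense	2.1	1	0	no
ADHD14.p1	YLPM1	p.R1646X	chr14	75276497	C	T	stopgain		<0.001	0	no
ADHD25.p1	SECISBP2L	p.T934fs	chr15	49284809	TG	T	frameshift deletion		0.981	0	no
ADHD33.p1	NARS2	p.R54X	chr11	78282471	G	A	stopgain		<0.001	3.36E-05	no
ADHD37.p1	CTNNA2	p.R348W	chr2	80808942	C	T	missense	2.6	0.975	0	yes (ASD)
ADHD44.p1	BEST4	p.L207fs	chr1	45251759	CAGAG	C	frameshift deletion		<0.001	0	no
ADHD50.p1	KDM5B	p.R1093X	chr1	202704703	G	A	stopgain		<0.001	1.12E-05	yes (ASD and DD)
ADHD57.p1	STAG1	p.R1088X	chr3	136068009	G	A	stopgain		1	0	yes (DD)
ADHD58.p1	KDM5B	p.D806fs	chr1	202711840	TC	T	frameshift deletion		<0.001	0	yes (ASD and DD)
ADHD61.p1	EML6	p.R313X	chr2	55071273	C	T	stopgain		<0.001	0	yes
ADHD69.p1	CFL1	p.Y82C	chr11	65623472	T	C	missense	3.2	0.990	0	no
ADHD71.p1	OCEL1	p.G34X	chr19	17337532	G	T	stopgain		<0.001	0	no
ADHD71.p1	TTC26	p.G24D	chr7	138819468	G	A	splicing		<0.001	0	no
ADHD84.p1	PLD5	p.D28fs	chr1	242511463	TG	T	frameshift deletion		<0.001	0	no
ADHD86.p1	FBXO11	p.P918S	chr2	48035289	G	A	missense	2.6	1	0	yes (ASD and DD)
ADHD95.p1	CHST15	p.L214fs	chr10	125804342	G	GGT	frameshift insertion		<0.001	0	no
ADHD98.p1	EHBP1L1	p.M1429fs	chr11	65359271	CATGG	C	frameshift deletion		<0.001	0	no
ADHD99.p1	TUBB	p.G233E	chr6	30691669	G	A	missense	3.3	1	0	no
ADHD107.p1	CTNND2	p.V229fs	chr5	11236867	AC	A	frameshift deletion		1	0	no
ADHD117.p1	GOLGB1	p.Y288X	chr3	121435768	A	C	stopgain		0.003	0	no
ADHD130.p1	L1TD1	p.S580X	chr1	62676185	C	A	stopgain		<0.001	0	no
ADHD134.p1	GNB2L1	p.N244D	chr5	180665146	T	C	missense	2.2	1	0	no
ADHD141.p1	PAK1	c.C44T	chr11	77103522	G	A	missense	2.8	0.059	0	yes (DD)
ADHD144.p1	USP54	p.R58X	chr10	75331247	G	A	stopgain		<0.001	3.30E-05	no
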