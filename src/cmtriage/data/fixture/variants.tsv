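family_id	era	gene	chrom	pos	ref	alt	hgvs_c	hgvs_p	region_class	consequence	carriers	freq_dbsnp135	freq_1000g	freq_esp	inhouse_n	missense_verdicts	splice_verdicts	lit_cases	lit_functional	lit_near_known	lit_same_codon	lit_benign	phenotype_match
5	ngs	GJB1	GJB1	688	C	T	c.688C>T	p.Arg230Cys	exonic	nonsynonymous	5-1:hemi;5-2:hemi				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
102	ngs	HSPB1	HSPB1	380	G	T	c.380G>T	p.Arg127Leu	exonic	nonsynonymous	102-1:het;102-2:het				0	P,P,P,P	N,N,N,N,N	0	0	1	1	0	match
90	ngs	MFN2	MFN2	310	C	T	c.310C>T	p.Arg104Trp	exonic	nonsynonymous	90-1:het				0	P,P,P,P	N,N,N,N,N	2	0	0	0	0	match
142	ngs	SH3TC2	SH3TC2	2860	C	T	c.2860C>T	p.Arg954*	exonic	nonsense	142-1:hom;142-3:het;142-4:het;142-5:het				5	U,U,U,U	N,N,N,N,N	2	0	0	0	0	match
252	ngs	SH3TC2	SH3TC2	2860	C	T	c.2860C>T	p.Arg954*	exonic	nonsense	252-1:hom;252-3:het;252-4:het;252-5:het				5	U,U,U,U	N,N,N,N,N	2	0	0	0	0	match
285	ngs	SH3TC2	SH3TC2	2860	C	T	c.2860C>T	p.Arg954*	exonic	nonsense	285-1:hom;285-3:het;285-4:het				5	U,U,U,U	N,N,N,N,N	2	0	0	0	0	match
295	ngs	SH3TC2	SH3TC2	2860	C	T	c.2860C>T	p.Arg954*	exonic	nonsense	295-1:hom;295-3:het;295-4:het				5	U,U,U,U	N,N,N,N,N	2	0	0	0	0	match
257	ngs	ARHGEF10	ARHGEF10	1013	G	C	c.1013G>C	p.Arg338Thr	exonic	nonsynonymous	257-1:het				0	B,B,B,B	N,N,N,N,N	0	0	1	0	0	match
9	ngs	DNM2	DNM2	1241	A	G	c.1241A>G	p.Lys414Arg	exonic	nonsynonymous	9-1:het			0.0001	1	P,P,P,B	N,N,N,N,N	0	0	1	0	0	match
231	ngs	DYNC1H1	DYNC1H1	1700	G	A	c.1700G>A	p.Arg567His	exonic	nonsynonymous	231-1:het				0	P,P,P,B	N,N,N,N,N	0	0	1	0	0	match
123	ngs	KIF1B	KIF1B	881	A	G	c.881A>G	p.Lys294Arg	exonic	nonsynonymous	123-1:het			0.00008	0	P,P,P,P	N,N,N,N,N	0	0	1	0	0	match
27	ngs	LMNA	LMNA	1930	C	T	c.1930C>T	p.Arg644Cys	exonic	nonsynonymous	27-1:het			0.001	0	P,P,P,P	N,N,N,N,N	1	0	0	0	0	match
54	ngs	LMNA	LMNA	1930	C	T	c.1930C>T	p.Arg644Cys	exonic	nonsynonymous	54-1:het			0.001	0	P,P,P,P	N,N,N,N,N	1	0	0	0	0	match
62	ngs	POLG	POLG	1491	G	C	c.1491G>C	p.Gln497His	exonic	nonsynonymous	62-1:het				0	P,P,P,B	N,N,N,N,N	1	0	0	0	0	match
62	ngs	POLG	POLG	2243	G	C	c.2243G>C	p.Trp748Ser	exonic	nonsynonymous	62-1:het				0	P,B,B,B	N,N,N,N,N	1	0	0	0	0	match
95	ngs	REEP1	REEP1	524	A	G	c.524A>G	p.*175Trpext*55	exonic	stop_loss	95-1:het				0	P,P,U,U	N,N,N,N,N	0	0	0	0	0	match
95	ngs	SETX	SETX	3075	A	ATGA	c.3075_3076insTGA	p.Arg1026*	exonic	nonsense	95-1:het				0	P,P,U,U	N,N,N,N,N	0	0	0	0	0	match
252	ngs	AARS	AARS	2150	A	G	c.2150A>G		exonic	nonsynonymous	252-1:het				0	P,B,B,B	N,N,N,N,N	0	0	0	0	0	unknown
27	ngs	DCTN1	DCTN1	1951	C	T	c.1951C>T	p.Arg651Trp	exonic	nonsynonymous	27-1:het				0	P,B,B,B	N,N,N,N,N	0	0	0	0	0	unknown
54	ngs	ARHGEF10	ARHGEF10	2197	C	T	c.2197C>T	p.His733Tyr	exonic	nonsynonymous	54-1:het				0	P,B,B,B	N,N,N,N,N	0	0	0	0	0	unknown
231	ngs	GAN	GAN	601	G	A	c.601G>A		exonic	nonsynonymous	231-1:het				0	P,P,B,B	N,N,N,N,N	0	0	0	0	0	unknown
11	ngs	SEPT9	SEPT9	500	C	T	c.500C>T		exonic	nonsynonymous	11-1:het				0	P,B,B,B	N,N,N,N,N	0	0	0	0	0	unknown
11	ngs	SETX	SETX	4000	G	A	c.4000G>A		exonic	nonsynonymous	11-1:het				0	P,B,B,B	N,N,N,N,N	0	0	0	0	0	unknown
118	prior	GJB1	GJB1	187	G	A	c.187G>A	p.Val63Ile	exonic	nonsynonymous	118-1:hemi				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
256	prior	GJB1	GJB1	187	G	A	c.187G>A	p.Val63Ile	exonic	nonsynonymous	256-1:hemi				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
83	prior	GJB1	GJB1	225	CG	C	c.225delG	p.Leu76CysfsTer8	exonic	frameshift	83-1:hemi				0	U,U,U,U	N,N,N,N,N	2	0	0	0	0	match
44	prior	GJB1	GJB1	491	G	A	c.491G>A	p.Arg164Gln	exonic	nonsynonymous	44-1:hemi				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
398	prior	GJB1	GJB1	658	C	T	c.658C>T	p.Arg220*	exonic	nonsense	398-1:hemi				0	U,U,U,U	N,N,N,N,N	2	0	0	0	0	match
8	prior	MFN2	MFN2	280	C	T	c.280C>T	p.Arg94Trp	exonic	nonsynonymous	8-1:het				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
38	prior	MFN2	MFN2	281	G	A	c.281G>A	p.Arg94Gln	exonic	nonsynonymous	38-1:het				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
258	prior	MFN2	MFN2	2119	C	T	c.2119C>T	p.Arg707Trp	exonic	nonsynonymous	258-1:het				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
39	prior	MPZ	MPZ	161	C	G	c.161C>G	p.Ser54Cys	exonic	nonsynonymous	39-1:het				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
1	prior	SOD1	SOD1	140	A	G	c.140A>G	p.His46Arg	exonic	nonsynonymous	1-1:het				0	P,P,P,B	N,N,N,N,N	2	0	0	0	0	match
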