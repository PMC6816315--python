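# Curated reference table: inborn-error-of-immunity diseases carrying two or more
# high-score (>= 0.3) gene-disease associations in public association data, with
# PPI cluster membership (genes sharing a cluster id interact within one STRING
# cluster; blank cluster = singleton) and the per-disease PPI enrichment p-value
# as printed ("<1.0E-16" means below the reporting floor).
disease	gene	score	cluster	ppi_p
Aicardi-Goutieres syndrome 2	RNASEH2B	0.6	c1	8.44E-15
Aicardi-Goutieres syndrome 2	TREX1	0.5	c1	8.44E-15
Aicardi-Goutieres syndrome 2	ADAR	0.3	c1	8.44E-15
Aicardi-Goutieres syndrome 2	IFIH1	0.3	c1	8.44E-15
Aicardi-Goutieres syndrome 2	USP18	0.3	c1	8.44E-15
Aicardi-Goutieres syndrome 2	SAMHD1	0.3	c1	8.44E-15
Aplastic anemia	TERT	0.69	c1	8.94E-05
Aplastic anemia	IFNG	0.6	c1	8.94E-05
Aplastic anemia	PRF1	0.4	c1	8.94E-05
Aplastic anemia	CSF3	0.37	c1	8.94E-05
Aplastic anemia	CSF2	0.34	c1	8.94E-05
Aplastic anemia	SBDS	0.32	c1	8.94E-05
Aplastic anemia	NBN	0.42		8.94E-05
Autoimmune lymphoproliferative syndrome	FAS	1.0	c1	1.18E-05
Autoimmune lymphoproliferative syndrome	FASLG	0.93	c1	1.18E-05
Autoimmune lymphoproliferative syndrome	CASP10	0.34	c1	1.18E-05
Autoimmune lymphoproliferative syndrome	PRKCD	0.31	c1	1.18E-05
Autoimmune lymphoproliferative syndrome	NRAS	0.32	c2	1.18E-05
Autoimmune lymphoproliferative syndrome	CASP8	0.3	c2	1.18E-05
Autoimmune lymphoproliferative syndrome, type IB	FASLG	0.4	c1	3.01E-02
Autoimmune lymphoproliferative syndrome, type IB	FAS	0.3	c1	3.01E-02
Bare lymphocyte syndrome, type I	TAP2	0.51	c1	2.67E-12
Bare lymphocyte syndrome, type I	TAPBP	0.51	c1	2.67E-12
Bare lymphocyte syndrome, type I	TAP1	0.5	c1	2.67E-12
Bare lymphocyte syndrome, type I	B2M	0.3	c1	2.67E-12
Bare lymphocyte syndrome, type II, complementation group A	CIITA	0.4	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group A	RFX5	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group A	RFXANK	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group C	RFX5	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group C	CIITA	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group C	RFXANK	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group D	CIITA	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group D	RFX5	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group D	RFXANK	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group E	RFX5	0.4	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group E	CIITA	0.3	c1	9.06E-07
Bare lymphocyte syndrome, type II, complementation group E	RFXANK	0.3	c1	9.06E-07
Bloom syndrome	BLM	1.0		1.0
Bloom syndrome	UNG	0.35		1.0
Bone marrow failure syndrome 2	ERCC6L2	0.6		1.0
Bone marrow failure syndrome 2	CSF2	0.3		1.0
Bone marrow failure syndrome 2	SRP72	0.3		1.0
Bone marrow failure syndrome 2	DNAJC21	0.3		1.0
CHARGE syndrome	CHD7	1.0		1.0
CHARGE syndrome	SEMA3E	0.6		1.0
Cystic fibrosis	CFTR	1.0	c1	2.76E-07
Cystic fibrosis	SCNN1B	0.6	c1	2.76E-07
Cystic fibrosis	SCNN1A	0.37	c1	2.76E-07
Cystic fibrosis	SCNN1G	0.36	c1	2.76E-07
Cystic fibrosis	STX1A	0.31	c1	2.76E-07
Cystic fibrosis	TGFB1	0.6		2.76E-07
Cystic fibrosis	DCTN4	0.52		2.76E-07
Cystic fibrosis	CLCA4	0.34		2.76E-07
Cystic fibrosis	TNFRSF1A	0.31		2.76E-07
DiGeorge syndrome	TBX1	0.9	c1	<1.0E-16
DiGeorge syndrome	COMT	0.6	c1	<1.0E-16
DiGeorge syndrome	CRKL	0.51	c1	<1.0E-16
DiGeorge syndrome	FGF8	0.5	c1	<1.0E-16
DiGeorge syndrome	HIRA	0.4	c1	<1.0E-16
DiGeorge syndrome	DGCR	0.4	c1	<1.0E-16
DiGeorge syndrome	UFD1	0.33	c1	<1.0E-16
DiGeorge syndrome	DGCR6	0.33	c1	<1.0E-16
DiGeorge syndrome	DGCR2	0.32	c1	<1.0E-16
DiGeorge syndrome	GP1BB	0.31	c1	<1.0E-16
DiGeorge syndrome	ARVCF	0.3	c1	<1.0E-16
DiGeorge syndrome	ESS2	0.3	c1	<1.0E-16
DiGeorge syndrome	DGCR8	0.31		<1.0E-16
DiGeorge syndrome	JMJD1C	0.3		<1.0E-16
DiGeorge syndrome	SEC24C	0.3		<1.0E-16
DiGeorge syndrome	RREB1	0.3		<1.0E-16
Immunodeficiency 44	STAT2	0.6	c1	1.16E-02
Immunodeficiency 44	IFNAR2	0.3	c1	1.16E-02
Leukemia, acute myeloid, susceptibility to	SETD2	0.3	c1	1.17E-05
Leukemia, acute myeloid, susceptibility to	CEBPA	0.3	c1	1.17E-05
Leukemia, acute myeloid, susceptibility to	SETBP1	0.3	c1	1.17E-05
Leukemia, acute myeloid, susceptibility to	JAK2	0.3	c1	1.17E-05
LIG4 syndrome	LIG4	0.99	c1	1.70E-02
LIG4 syndrome	XRCC4	0.3	c1	1.70E-02
Muckle-Wells syndrome	NLRP3	0.8	c1	0.12
Muckle-Wells syndrome	NLRC4	0.3	c1	0.12
Muckle-Wells syndrome	MME	0.3		0.12
Muckle-Wells syndrome	PLCG2	0.3		0.12
Myopathy, tubular aggregate, 1	STIM1	0.3	c1	3.37E-03
Myopathy, tubular aggregate, 1	CASQ1	0.3	c1	3.37E-03
Omenn syndrome	RAG2	0.8	c1	<1.0E-16
Omenn syndrome	RAG1	0.6	c1	<1.0E-16
Omenn syndrome	DCLRE1C	0.55	c1	<1.0E-16
Omenn syndrome	IL7R	0.33	c1	<1.0E-16
Omenn syndrome	IL2RG	0.32	c1	<1.0E-16
Omenn syndrome	ADA	0.31	c1	<1.0E-16
Omenn syndrome	CD3E	0.31	c1	<1.0E-16
Omenn syndrome	ZAP70	0.31	c1	<1.0E-16
Omenn syndrome	CD3D	0.3	c1	<1.0E-16
Omenn syndrome	TFRC	0.3	c1	<1.0E-16
Omenn syndrome	AK2	0.3	c1	<1.0E-16
Omenn syndrome	LIG4	0.3	c1	<1.0E-16
Omenn syndrome	JAK3	0.3	c1	<1.0E-16
Omenn syndrome	CHD7	0.31		<1.0E-16
Omenn syndrome	RMRP	0.3		<1.0E-16
Osteopetrosis, autosomal recessive 6	PLEKHM1	0.8	c1	9.14E-08
Osteopetrosis, autosomal recessive 6	CLCN7	0.3	c1	9.14E-08
Osteopetrosis, autosomal recessive 6	TCIRG1	0.3	c1	9.14E-08
Specific granule deficiency	CEBPE	0.61		1.0
Specific granule deficiency	SMARCD2	0.6		1.0
Specific granule deficiency 2	SMARCD2	0.4		1.0
Specific granule deficiency 2	CEBPE	0.3		1.0
Tetralogy of fallot	ZFPM2	0.98	c1	<1.0E-16
Tetralogy of fallot	NKX2-5	0.96	c1	<1.0E-16
Tetralogy of fallot	GATA4	0.8	c1	<1.0E-16
Tetralogy of fallot	JAG1	0.8	c1	<1.0E-16
Tetralogy of fallot	GATA6	0.73	c1	<1.0E-16
Tetralogy of fallot	GDF1	0.71	c1	<1.0E-16
Tetralogy of fallot	GJA5	0.62	c1	<1.0E-16
Tetralogy of fallot	CITED2	0.6	c1	<1.0E-16
Tetralogy of fallot	TBX1	0.46	c1	<1.0E-16
Tetralogy of fallot	GATA5	0.42	c1	<1.0E-16
Tetralogy of fallot	NKX2-6	0.4	c1	<1.0E-16
Tetralogy of fallot	FOXC2	0.4	c1	<1.0E-16
Tetralogy of fallot	HAND2	0.31	c1	<1.0E-16
Tetralogy of fallot	FOXC1	0.3	c1	<1.0E-16
Tetralogy of fallot	FLT4	0.3	c1	<1.0E-16
Tetralogy of fallot	FOXH1	0.3	c1	<1.0E-16
Wiskott-Aldrich syndrome	WAS	1.0	c1	1.70E-02
Wiskott-Aldrich syndrome	WIPF1	0.6	c1	1.70E-02
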