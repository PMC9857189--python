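chrom	start	end	gene	strand	cnv_direction	occurring_freq	tcga_freq	gene_class
chr1	156030965	156040295	RAB25	+	AMP	0.075	0.072	oncogene
chr3	168801286	169381563	MECOM	-	AMP	0.125	0.247	oncogene
chr3	169940219	170023770	PRKCI	+	AMP	0.15	0.221	oncogene
chr3	170606203	170626426	EIF5A2	-	AMP	0.225	0.207	oncogene
chr3	178866310	178952497	PIK3CA	+	AMP	0.10	0.18	oncogene
chr4	55524094	55606881	KIT	+	AMP	0.025	0.012	oncogene
chr5	67511583	67597649	PIK3R1	+	DEL	0.20	0.02	oncogene
chr5	141971742	142077635	FGF1	-	AMP	0.05	0.01	oncogene
chr7	55086724	55275031	EGFR	+	AMP	0.025	0.004	oncogene
chr8	128748314	128753680	MYC	+	AMP	0.075	0.315	oncogene
chr12	25358179	25403854	KRAS	-	AMP	0.025	0.098	oncogene
chr14	105235686	105262080	AKT1	-	AMP	0.225	0.029	oncogene
chr17	37844392	37884915	ERBB2	+	AMP	0.00	0.022	oncogene
chr19	15270443	15311792	NOTCH3	-	AMP	0.00	0.115	oncogene
chr19	30302900	30315215	CCNE1	+	AMP	0.025	0.217	oncogene
chr19	40736223	40791302	AKT2	-	AMP	0.10	0.07	oncogene
chr20	54944444	54967351	AURKA	-	AMP	0.10	0.039	oncogene
chr1	68511644	68516460	DIRAS3	-	AMP	0.025	0.01	tumor_suppressor
chr3	38080695	38164228	DLEC1	+	AMP	0.025	0.006	tumor_suppressor
chr3	50367216	50378367	RASSF1	-	AMP	0.075	0.01	tumor_suppressor
chr5	39371775	39425335	DAB2	-	AMP	0.10	0.031	tumor_suppressor
chr5	151040656	151066615	SPARC	-	AMP	0.025	0.012	tumor_suppressor
chr6	144261436	144385735	PLAGL1	-	DEL	0.125	0.006	tumor_suppressor
chr6	166822853	167275771	RPS6KA2	-	DEL	0.225	0.014	tumor_suppressor
chr10	89623194	89728532	PTEN	+	DEL	0.125	0.061	tumor_suppressor
chr11	132284874	133402403	OPCML	-	AMP	0.075	0.025	tumor_suppressor
chr13	32889616	32973809	BRCA2	+	DEL	0.10	0.008	tumor_suppressor
chr13	50202434	50208008	ARL11	+	DEL	0.025	0.022	tumor_suppressor
chr16	78133326	79246564	WWOX	+	DEL	0.10	0.057	tumor_suppressor
chr17	1933430	1946725	DPH1	+	AMP	0.00	0.01	tumor_suppressor
chr17	7571719	7590868	TP53	-	DEL	0.10	0.006	tumor_suppressor
chr17	41196311	41277500	BRCA1	-	DEL	0.075	0.006	tumor_suppressor
chr19	57321444	57352094	PEG3	-	AMP	0.05	0.018	tumor_suppressor
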