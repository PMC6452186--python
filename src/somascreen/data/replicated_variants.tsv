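patient	chrom	pos	ref	alt	gene	aa_change	cell	aaf_screen_pct	aaf_repl_pct	p_repl	cadd	msc	gerp	kaviar	cosmic	timepoint	delta_years
MS-1	2	24952447	C	T	NCOA1	P988P	T	2.00	0.57	9.56E-207	13.15	3.31	4.98	6.50E-6	-	later	1.0
MS-1	3	48508943	C	G	TREX1	L352V	T	2.78	2.53	1.05E-149	23.50	5.61	1.35	0	-	same	0.0
MS-1	11	8734271	G	A	ST5	R247C	T	0.75	1.12	1.42E-272	35.00	17.32	5.28	6.50E-6	-	later	1.0
MS-1	19	49703983	G	A	TRPM4	R611H	T	1.60	0.85	2.67E-87	30.00	0.09	4.57	5.82E-5	-	same	0.0
MS-3	1	93202076	T	C	EVI5	T54A	T	0.98	1.14	8.66E-108	0.08	3.31	-0.13	1.29E-5	-	later	1.0
MS-3	2	33590430	A	T	LTBP1	D1156V	T	0.70	0.80	3.71E-56	27.20	3.31	5.67	0	-	later	1.0
MS-3	3	46244852	C	G	CCR1	R318T	B	1.22	1.41	5.80E-143	0.24	3.31	-2.00	0	-	later	1.0
MS-3	11	63403722	T	C	ATL3	N294S	T	2.51	2.72	0	23.10	27.30	5.55	4.53E-5	-	later	1.0
MS-3	11	128680557	A	G	FLI1	K152E	T	1.16	1.45	2.24E-291	23.90	23.30	3.89	0	-	later	1.0
MS-3	12	123812503	G	C	SBNO1	G456G	T	0.79	5.58	0	3.43	3.31	2.02	0	-	later	1.0
MS-3	16	67116210	A	T	CBFB	E165V	B	1.85	2.79	2.10E-163	33.00	15.45	5.54	0	-	later	1.0
MS-3	Y	16734258	C	T	NLGN4Y	R87W	B	1.07	0.77	1.33E-06	27.10	15.26	0.54	0	-	later	1.0
MS-4	6	74073541	G	A	KHDC3L	Q204Q	T	5.63	3.77	0	0.97	22.30	1.63	0	-	later	1.0
MS-4	16	88504410	T	C	ZNF469	L3483P	T	1.25	4.28	2.38E-06	3.60	0.00	0.28	0	-	later	1.0
MS-8	2	135888230	G	A	RAB3GAP1	R392Q	T	0.70	0.51	4.90E-10	22.70	8.10	3.43	3.23E-5	+	same	0.0
MS-8	6	31631776	G	C	GPANK1	S160R	T	18.33	13.88	0	8.47	3.31	3.38	0	-	same	0.0
MS-8	6	149700524	T	C	TAB2	L491L	T	2.24	2.55	0	0.04	0.01	-6.98	0	-	same	0.0
MS-8	7	47409021	G	A	TNS3	R408C	T	0.98	0.64	1.99E-197	23.50	3.31	4.91	1.29E-5	-	same	0.0
MS-8	8	135521904	C	A	ZFAT	S1088S	B	0.63	0.69	1.19E-88	20.70	3.31	-11.6	0	-	same	0.0
MS-8	16	67517193	C	T	AGRP	A37T	B	2.15	1.88	2.52E-21	22.20	3.31	4.20	0	-	same	0.0
MS-8	21	15538710	G	C	LIPI	P236A	T	15.54	16.58	0	23.80	3.31	5.48	6.50E-6	-	same	0.0
MS-9	1	240071069	C	T	CHRM3	F106F	T	7.47	3.67	0	9.42	3.31	4.69	0	-	same	0.0
MS-9	2	97427889	A	T	CNNM4	M385L	B	1.20	1.68	1.16E-245	18.11	0.00	5.19	0	-	same	0.0
MS-9	5	133481460	T	C	TCF7	D253D	T	1.12	0.81	0	6.13	5.37	1.39	3.88E-4	-	same	0.0
MS-9	16	61891025	G	A	CDH8	T222I	T	3.77	3.36	4.32E-252	29.30	3.31	5.88	0	-	same	0.0
MS-9	X	29972647	G	T	IL1RAPL1	D404Y	T	1.30	0.79	4.57E-276	30.00	32.00	5.72	0	+	same	0.0
MS-10	2	141533745	C	T	LRP1B	G1808R	T	2.72	1.97	0	34.00	5.45	5.69	6.50E-6	-	same	0.0
MS-10	6	26508797	C	A	BTN1A1	R326R	T	1.51	1.58	0	10.95	3.31	2.10	3.23E-5	-	same	0.0
MS-10	7	103048325	C	T	SLC26A5	P287P	T	1.19	1.51	0	14.92	3.31	-3.99	1.94E-5	-	same	0.0
MS-10	7	122635510	T	G	TAS2R16	Q60P	T	3.76	3.89	0	23.20	3.31	3.42	0	-	same	0.0
MS-10	9	73477936	C	T	TRPM3	R117Q	T	0.52	0.64	8.75E-119	22.80	3.31	5.95	6.50E-6	+	same	0.0
MS-10	11	118373702	A	C	KMT2A	K2365N	T	1.60	1.72	9.15E-33	18.97	26.10	4.03	0	-	same	0.0
MS-10	12	2622058	A	T	CACNA1C	D433V	T	2.98	3.83	0	28.40	0.07	4.43	0	-	same	0.0
MS-10	17	65026679	C	T	CACNG4	Y181Y	T	8.23	8.23	0	10.62	13.3	-4.15	3.88E-5	-	same	0.0
MS-10	19	37618680	A	C	ZNF420	N263H	T	0.62	0.61	3.24E-36	14.07	3.31	2.91	0	-	same	0.0
MS-10	X	17746076	G	T	NHS	D1086Y	B	0.92	0.48	1.52E-05	24.60	0.00	5.49	0	-	same	0.0
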