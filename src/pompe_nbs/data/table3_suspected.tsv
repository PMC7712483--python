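# Suspected-LOPD patients (one pathogenic allele + one VUS, or two VUS):
# newborn-screening GAA activities (µmol/L/h), genotype as reported
# (verbatim spellings preserved), confirmatory biomarkers with site
# reference ranges.  Empty cell / "-" / "ND" = missing at source;
# "<x" = censored at x.  Printed unit suffixes ("umol/L/h") are dropped.
id	group	cardiomyopathy	gaa1	gaa2	genotype	conf_gaa	conf_gaa_limit	ast	ast_ref	alt	alt_ref	ck	ck_ref	bnp	bnp_ref	hex4	hex4_ref	note
S1	suspected_LOPD	0	0.91	0.2	c.-32-13T>G/c.692+3G>C	2.1		30	24-72	30	17-63	150		ND		3.3
S2	suspected_LOPD	0	2.06	1.99	c.-32-13T>G/c.1594G>A	3.8		41	24-72	30	17-63	134		ND		3.0
S3	suspected_LOPD	0	1.48	0.67	c.-32-13T>G/c.546G>A	1.6		42	24-72	37	17-63	ND		ND		6.0		CK printed "ND"
S4	suspected_LOPD	0	1.85	0.98	c.-32-13T>G/c.266G>A;c.1377C>G	1.4		39	24-72	32	17-63	293		ND		8.3		two VUS reported in cis on the second allele
S5	suspected_LOPD	0	1.04	0.53	c.-32-13T>G/c.2003 A>G	0.6	3.88					107	26-192			2.4	0-20
S6	suspected_LOPD	0	0.61	0.41	c.-32-13T>G/c.1721T>C	0.8		96	24-72	84	17-63	377		ND		4.9
S7	suspected_LOPD	0	0.52	0.45	c.-32-13T>G/c.1291_1299del9	1.9		83	20-70	48	17-63	486		ND		9.4
S8	suspected_LOPD	0	0.56	0.63	c.-32-13T>G/1655T>C	2.5		156	24-72	103	17-63	668		ND		6.0		second allele printed without "c." prefix; verbatim
S9	suspected_LOPD	0	ND	1.34	c.-32-13T>G/c.533G>A	3.7		25	24-72	19	17-63	86		ND		2.5
S10	suspected_LOPD	0	1.3	2.01	c.-32-13T>G/ c.862G>A;c.271G>A	2.0		32	24-72	31	17-63	406		ND		3.4		pseudodeficiency rider in cis with the VUS
S11	suspected_LOPD	0	1.58	0.64	c.-32-13T>G/ c.841C>T	1.4		23	24-72	42	17-63	136		ND		6.4
S12	suspected_LOPD	0	0.58	1.84	c.1A>G/c.1345C>T	1.90	3.88	44	15-41	26	12-42	241	15-200	-		8.4	0-20
S13	suspected_LOPD	0	1.02	1.22	c.2560C>T/c.1888+5G>T;c.2065G>A	3.80	3.88	112	20-64	29	12-42	69	60-305	407.3	0-100	4.6	0-20	confirmatory limit printed "(3.88)"
S14	suspected_LOPD	0	<0.19	0.12	c.2236T>C/c.700A>G/C	0.90	3.88	52	22-71	36	7-50	142	60-305	44.2	0-100	15.7	0-20	multi-allelic shorthand second allele kept opaque
S15	suspected_LOPD	0	1.94	2.06	c.1478C>T/1194+3G>C	6.05	3.88					86	60-305	-		<4.4	0-20	second allele printed without "c." prefix; verbatim
S16	suspected_LOPD	0	1.97	1.16	c.784G>A/c.859-19G>A/c.1392G>C	4.00	3.88	92	20-64	42	12-42	201	60-305	55.3	0-100	6.1	0-20	c.859-19G>A is the likely-benign rider
S17	suspected_LOPD	0	0.98	0.58	c.2105G>T/c.1124G>A	1.20	3.88	64	22-71	20	7-50	85	60-305	-		3.0	0-20
S18	suspected_LOPD	0	1.59	0.95	c.-32-13T>G/c.692+3G>C	2.70	3.88	73	22-71	19	7-50	65	60-305	52.7	0-100	3.3	0-20
S19	suspected_LOPD	0	1.19	1.27	c.1655T>C/c.1888+5G>T/c.2065G>A	0.43	1.29	60	22-71	25	7-50	110	60-305	19.3	0-100	-		confirmatory reference printed as range "(1.29-25.7)"
S20	suspected_LOPD	0	-	1.27	c.-32-13T>G/c.705G>A/c.(1726G>A;c.2065G>A)	1.80	3.88	80	22-71	41	7-50	86	60-305	30.0	0-100	3.3	0-20	two pseudodeficiency riders in a parenthesized cis group
S21	suspected_LOPD	0	1.64	1.1	c.-32-13T>G/c.650C>T	4.10	3.88	65	22-71	35	7-50	68	60-305	33.8	0-100	5.7	0-20
S22	suspected_LOPD	0	1.02	0.85	c.1655T>C/c.664G>A	2.01	3.88	69	20-64	41	12-42	94	60-305	57.4	0-100	6.2	0-20
S23	suspected_LOPD	0	-	0.42	c.-32-13T>G/c.1103G>A	-		126	20-64	85	12-42	407	60-305	-		7.2	0-20
S24	suspected_LOPD	0	-	1.08	c.258dupC/c.1909C>A/c.(1726G>A;c.2065G>A)	-		64	22-71	38	7-50	102	60-305	13.0	0-100	3.4	0-20	two pseudodeficiency riders in a parenthesized cis group
S25	suspected_LOPD	0	1.98	1.17	c.1552-3C>G/c.1378G>A	-		91	22-71	46	7-50	123	60-305	29.1	0-100	3.7	0-20
S26	suspected_LOPD	0	-	1.49	c.1655T>C/c.266G>A	2.10	3.88	56	22-71	36	7-50	88	60-305	-		3.8	0-20
S27	suspected_LOPD	0		0.42	c.-32-13T>G/c.2467A>T
S28	suspected_LOPD	0		1.63	c.1504A>G/c.2467A>T
S29	suspected_LOPD	0		1.36	c.2560C>T/c.726G>A
S30	suspected_LOPD	0		0.93	c.2238G>C/c.2467A>T
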