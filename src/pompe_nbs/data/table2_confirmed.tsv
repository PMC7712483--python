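# Confirmed IOPD and LOPD patients: newborn-screening GAA activities
# (µmol/L/h), genotype as reported (verbatim spellings preserved, including
# typographical variants), and confirmatory biomarkers with site reference
# ranges.  Empty cell / "-" / "ND" = missing at source; "<x" = censored at x.
# Cardiomyopathy flags for the two IOPD patients come from the program's
# clinical narrative (hypertrophic cardiomyopathy on ECHO in both).
id	group	cardiomyopathy	gaa1	gaa2	genotype	conf_gaa	conf_gaa_limit	ast	ast_ref	alt	alt_ref	ck	ck_ref	bnp	bnp_ref	hex4	hex4_ref	note
I1	IOPD	1	0.65	0.22	c.759delC/c.1551+1G>C	4.4	6.7	103	30-100			923	60-305	1080	0-100	24.7		admitted for hypertrophic cardiomyopathy; ALT not reported
I2	IOPD	1	0.65	0.34	c.525delT/c.1694_1697delTCTC	0.4	3.88	189	22-71	91	7-50	846	60-305	1232.5	0-100	30.2	0-20	confirmatory limit printed "<3.88"
L1	LOPD	0	1.86	0.78	c.-32-13T>G/c.-32-13T>G	3.1	6.7	72	24-72	41	17-63	530	28-300	ND		4.9	0-20
L2	LOPD	0	1.86	1.44	c.2238G>C/c.1552-3C>G	5.3	6.7	21	24-72	23	17-63	72	28-300	ND		4.2	0-20
L3	LOPD	0	1.73	1.08	c.-32-13T>G/c.-32-13T>G	3.6	6.7	56	24-72	49	17-63	125	28-300	ND		4.5	0-20
L4	LOPD	0	1.24	0.67	c.-32-13T>G/c.-32-13T>G	2.4	6.7	66	24-72	52	17-63	361	28-300	ND		3.9	0-20
L5	LOPD	0	1.82	0.94	c.-32-13T>G/c.-32-13T>G	6.9	6.7	52	24-72	46	17-63	333	28-300	ND		4.4	0-20
L6	LOPD	0	1.32	0.88	c.-32-13T>G/c.-32-13T>G	0.7	6.7	61	24-72	39	17-63	176	28-300	ND		5.9	0-20
L7	LOPD	0	1.05	0.19	c.-32-13 T>C/c.546 G>A	2.2	3.88					283	30-135	ND		2.6	0-3.0	"T>C" and spaced spellings verbatim
L8	LOPD	0	0.83	0.85	c.-32-13 T>G/c. 1655 T>C	0.93	3.88					365	60-305	ND		5.23		hex4 reference printed "<-8.9"; spaced spellings verbatim
L9	LOPD	0	0.97	0.33	c.2238G>C/c.2281delGinsAT/ c.2065G>A	0.93	3.88	72	22-71	43	7-50	145	60-305	13.0	0-100	5.3	0-20
L10	LOPD	0	0.84	0.49	c.1438-1G>C/c.-32-13T>G	2.1	3.88	168	20-64	104	12-42	617	60-305	-		6.6	0-20
L11	LOPD	0	-	0.63	c.-32-13T>G/c.2560C>T	3.00	3.88	125	22-71	50	7-50	421	60-305	-		-
L12	LOPD	0	-	-	c.-32-13T>G /c.2238G>C	2.60	3.88	112	22-71	50	7-50	464	60-305	51.6	0-100	6.1	0-20
L13	LOPD	0	0.56	0.62	c.-32-13T>G/c.-32-13T>G	3.80	3.88	78	20-64	42	12-42	122	60-305	71.8	0-100	4.8	0-20
L14	LOPD	0	1.68	0.79	c.156_157delTC/c.-32-13T>G	2.40	3.88	166	20-64	73	12-42	467	60-305	-		7.0	0-20
L15	LOPD	0	1.11	0.5	c.2238G>C/c.-32-13T>G/ c.2065G>A	1.60	3.88	49	20-64	27	12-42	68	60-305	-		2.8	0-20
L16	LOPD	0	1.06	0.26	c.-32-13T>G/c.-32-13T>G	6.4	3.88	73	22-71	39	7-50	140	60-305	99.8	0-100	8.5	0-20
L17	LOPD	0	1.04	0.77	c.-32-13T>G/c.-32-13T>G	1.80	3.88	150	22-71	42	7-50	275	60-305	44.5	0-100	5.2	0-20
L18	LOPD	0	0.7	0.34	c.-32-13T>G/c.2560C>T	1.40	3.88	152	22-71	55	7-50	542	60-305	16.5	0-100	7.6	0-20
L19	LOPD	0	1.07	0.38	c.456_458insGA/c.-32-13T>G	1.10	3.88	158	22-71	39	7-50	510	60-305	<10.0	0-100	8.1	0-20
L20	LOPD	0	0.88	0.77	c.-32-13T>G/c.-32-13T>G	3.50	3.88	63	20-64	34	12-42	204	60-305	65.4	0-100	-
L21	LOPD	0	1.77	0.84	c.-32-13T>G/c.-32-13T>G	-		71	22-71	60	7-50	155	60-305	-		12.6	0-20
L22	LOPD	0	1.07	0.92	c.-32-13T>G/c.-32-13T>G	1.60	3.88	92	22-71	46	7-50	265	60-305	81.5	0-100	5.9	0-20	confirmatory limit printed "(3.88)"
L23	LOPD	0	1.12	0.62	c.2238G>C; c.2065G>A /c.2238G>C; c.2065G>A	2.5	3.88	73	22-71	28	7-50	48	60-305	102.3	0-100	-		confirmatory limit printed "(3.88)"
L24	LOPD	0		0.43	c.1856G>A/c.2238G>C							197	60-305
L25	LOPD	0		0.95	c.2238G>C/c.2238G>C
L26	LOPD	0		1.01	c.2238G>C/c.2238G>C
L27	LOPD	0	1.1	0.42	c.1441T>C/c.2238G>C/ c.2065G>A	2.40	3.88	32	22-71	29	7-50	108	60-305	35.7	0-100	3.3	0-20
L28	LOPD	0		1.06	c.-32-13T>G/c.2238G>C/ c.2065G>A
L29	LOPD	0		0.48	c.-32-13T>G/c.1547G>A
L30	LOPD	0		1.07	c.32-13T>G/c.32-13T>G										splice spelled without leading "-" verbatim
L31	LOPD	0		0.94	c.32-13T>G/c.2238G>C / c.2065G>A										splice spelled without leading "-" verbatim
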