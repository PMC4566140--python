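family	conserved	n_members	reads_ck	reads_cr200	norm_ck	norm_cr200	log2fc
miR156/157	1	5	366511	265213	20218.44	13564.31	-0.58
miR158	1	2	699489	1730976	38587.04	88530.74	1.20
miR159	1	1	2645	1201	145.91	61.43	-1.25
miR160	1	4	2652	1644	146.30	84.08	-0.80
miR161	1	1	0	151	0.01	7.72	9.59
miR162	1	1	750	1438	41.37	73.55	0.83
miR164	1	2	20482	36698	1129.88	1876.92	0.73
miR165/166	1	5	91078	250786	5024.28	12826.45	1.35
miR167	1	2	19807	21945	1092.65	1122.38	0.04
miR168	1	2	196680	86888	10849.78	4443.89	-1.29
miR169	1	4	9690	4742	534.55	242.53	-1.14
miR171	1	1	155	299	8.55	15.29	0.84
miR172	1	2	1024	16755	56.49	856.93	3.92
miR319	1	2	13971	8927	770.70	456.57	-0.76
miR390	1	2	324	6464	17.87	330.60	4.21
miR391	1	2	1066	2988	58.81	152.82	1.38
miR393	1	1	15	13	0.83	0.66	-0.32
miR394	1	2	201	946	11.09	48.38	2.13
miR395	1	2	71	247	3.92	12.63	1.69
miR396	1	2	958	2301	52.85	117.68	1.16
miR397	1	1	15201	927	838.56	47.41	-4.14
miR398	1	3	1934	64	106.69	3.27	-5.03
miR399	1	2	142	87	7.83	4.45	-0.82
miR408	1	1	266952	32197	14726.31	1646.72	-3.16
miR400	0	1	109	84	6.01	4.30	-0.49
miR403	0	1	1634	1825	90.14	93.34	0.05
miR414	0	1	344	0	18.98	0.01	-10.89
miR415	0	1	0	229	0.01	11.71	10.19
miR482	0	1	134	2254	7.39	115.28	3.96
miR535	0	2	34	2034	1.88	104.03	5.79
miR824	0	2	529	2477	29.18	126.69	2.12
miR825	0	1	1455	1835	80.26	93.85	0.23
miR827	0	1	275	509	15.17	26.03	0.78
miR845	0	2	3003	5968	165.66	305.23	0.88
miR854	0	1	229	387	12.63	19.79	0.65
miR857	0	1	1413	240	77.95	12.27	-2.67
miR858	0	2	23	13	1.27	0.66	-0.93
miR860	0	1	58	345	3.20	17.65	2.46
miR1885	0	1	5417	6787	298.83	347.12	0.22
miR2111	0	3	280	104	15.45	5.32	-1.54
miR2118	0	1	27628	23077	1524.09	1180.27	-0.37
miR4993	0	1	0	306	0.01	15.65	10.61
miR5265	0	1	0	261	0.01	13.35	10.38
miR5293	0	1	143	551	7.89	28.18	1.84
miR5671	0	1	0	3860	0.01	197.42	14.27
miR7767	0	2	9153	23835	504.92	1219.04	1.27
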