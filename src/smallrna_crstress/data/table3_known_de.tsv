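family	mirna	count_ck	count_cr200	norm_ck	norm_cr200	log2fc	pvalue	sig	direction
miR156/157	miR156a	94427	59654	5209.0295	3051.0028	-0.77	0		down-regulated
miR156/157	miR156a-3p	257	0	14.1773	0.0100	-10.47	2.10E-82	**	down-regulated
miR156/157	miR156f-3p	0	286	0.0100	14.6275	10.51	3.36E-82	**	up-regulated
miR156/157	miR157a	268528	202820	14813.2449	10373.2254	-0.51	0		down-regulated
miR156/157	miR157a-3p	3299	2453	181.9881	125.4586	-0.54	9.42E-45		down-regulated
miR159	miR159a	2645	1201	145.9104	61.4251	-1.25	9.43E-148	**	down-regulated
miR160	miR160a	0	411	0.0100	21.0206	11.04	8.12E-118	**	up-regulated
miR160	miR160b	80	0	4.4132	0.0100	-8.79	3.66E-26	**	down-regulated
miR160	miR160b-3p	2572	0	141.8834	0.0100	-13.79	0	**	down-regulated
miR160	miR160d-3p	0	1233	0.0100	63.0618	12.62	0	**	up-regulated
miR161	miR161	0	151	0.0100	7.7229	9.59	9.81E-44	**	up-regulated
miR164	miR164b-3p	130	42	7.1708	2.1481	-1.74	2.24E-13	**	down-regulated
miR165/166	miR165a	1978	11721	109.1156	599.4703	2.46	0	**	up-regulated
miR165/166	miR165a-3p	173	10692	9.5435	546.8422	5.84	0	**	up-regulated
miR165/166	miR166e-3p	0	1029	0.0100	52.6282	12.36	6.65E-294	**	up-regulated
miR165/166	miR166g-3p	285	0	15.7219	0.0100	-10.62	2.66E-91	**	down-regulated
miR168	miR168a	195230	85348	10769.7886	4365.1220	-1.30	0	**	down-regulated
miR169	miR169b	884	0	48.7655	0.0100	-12.25	1.24E-281	**	down-regulated
miR169	miR169j-3p	0	819	0.0100	41.8877	12.03	4.55E-234	**	up-regulated
miR169	miR169m	0	3923	0.0100	200.6418	14.29	0	**	up-regulated
miR169	miR169r-3p	8806	0	485.7796	0.0100	-15.57	0	**	down-regulated
miR172	miR172c	1024	16685	56.4886	853.3540	3.92	0	**	up-regulated
miR172	miR172e-3p	0	70	0.0100	3.5801	8.48	1.18E-20	**	up-regulated
miR319	miR319a-3p	710	219	39.1669	11.2008	-1.81	1.17E-69	**	down-regulated
miR319	miR319b-5p	13261	8708	731.5380	445.3705	-0.72	2.73E-290		down-regulated
miR390	miR390a	314	6289	17.3217	321.6508	4.21	0	**	up-regulated
miR390	miR390a-3p	10	175	0.5516	8.9504	4.02	1.07E-37	**	up-regulated
miR391	miR391-3p	0	21	0.0100	1.0740	6.75	1.08E-06	**	up-regulated
miR394	miR394a	14	613	0.7723	31.3519	5.34	1.21E-151	**	up-regulated
miR395	miR395a	71	0	3.9167	0.0100	-8.61	2.65E-23	**	down-regulated
miR395	miR395b	0	247	0.0100	12.6328	10.30	4.35E-71	**	up-regulated
miR397	miR397a	15201	927	838.5574	47.4114	-4.14	0	**	down-regulated
miR398	miR398b-3p	133	0	7.3369	0.0100	-9.52	5.28E-43	**	down-regulated
miR398	miR398b-5p	0	64	0.0100	3.2733	8.35	6.03E-19	**	up-regulated
miR398	miR398c-5p	1801	0	99.3515	0.0100	-13.28	0	**	down-regulated
miR399	miR399b	0	87	0.0100	4.4496	8.80	1.69E-25	**	up-regulated
miR399	miR399h-5p	142	0	7.8334	0.0100	-9.61	7.29E-46	**	down-regulated
miR408	miR408-5p	266952	32197	14726.3054	1646.7150	-3.16	0	**	down-regulated
miR414	miR414	344	0	18.9766	0.0100	-10.89	4.76E-110	**	down-regulated
miR415	miR415	0	229	0.0100	11.7100	10.19	5.85E-66	**	up-regulated
miR482	miR482a-5p	134	2254	7.3921	115.2808	3.96	0	**	up-regulated
miR535	miR535b	0	2034	0.0100	104.0289	13.34	0	**	up-regulated
miR535	miR535d	34	0	1.8756	0.0100	-7.55	1.51E-11	**	down-regulated
miR824	miR824-3p	109	1565	6.0129	80.0419	3.73	1.57E-307	**	up-regulated
miR845	miR845d	1282	74	70.7148	3.7847	-4.22	9.51E-306	**	down-regulated
miR857	miR857	1413	240	77.9407	12.2748	-2.67	4.08E-222	**	down-regulated
miR860	miR860	58	345	3.1995	17.6450	2.46	2.01E-46	**	up-regulated
miR2111	miR2111a-3p	140	0	7.7230	0.0100	-9.59	3.15E-45	**	down-regulated
miR2111	miR2111a-5p	140	61	7.7230	3.1198	-1.31	7.17E-10	**	down-regulated
miR2111	miR2111b-3p	0	43	0.0100	2.1992	7.78	5.81E-13	**	up-regulated
miR4993	miR4993	0	306	0.0100	15.6504	10.61	6.72E-88	**	up-regulated
miR5265	miR5265	0	261	0.0100	13.3488	10.38	4.46E-75	**	up-regulated
miR5293	miR5293	143	771	7.8885	39.4328	2.29	5.15E-51	**	up-regulated
miR5671	miR5671	0	3860	0.0100	197.4200	14.27	0	**	up-regulated
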