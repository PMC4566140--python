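mirna	sequence	count_ck	count_cr200	norm_ck	norm_cr200	log2fc	pvalue	sig	direction
rsa-miRn-1	AAAUCAUACUUUCAUUGAUA	277	0	15.2806	0.0100	-10.58	9.26E-89	**	down-regulated
rsa-miRn-2	UGGAUAUGAUGUAGUUGAUCCGA	1275	0	70.3349	0.0100	-12.78	0	**	down-regulated
rsa-miRn-3	AGCAAACGAGAAUUGAACGGA	419	192	23.1140	9.8198	-1.24	1.78E-24	**	down-regulated
rsa-miRn-10	UGGAUGUAGAGGCAUUUCUUC	79	0	4.3580	0.0100	-8.77	7.60E-26	**	down-regulated
rsa-miRn-12	ACATTGGACTACATATATTAC	81	935	4.4683	47.8206	3.42	2.09E-171	**	up-regulated
rsa-miRn-14	CGUACGAGGAGCCAAGCAUGA	833	0	45.9521	0.0100	-12.17	1.99E-265	**	down-regulated
rsa-miRn-19	GCUCAAGAAAGCUGUGGGAAA	155	0	8.5505	0.0100	-9.74	5.40E-50	**	down-regulated
rsa-miRn-20	UCCCUUUGGAUGUCGUCUUGUG	20	0	1.1033	0.0100	-6.79	4.25E-07	**	down-regulated
rsa-miRn-23	UCAAUGAAAGGUAUGAUUCCC	0	377	0.0100	19.2817	10.91	3.96E-108	**	up-regulated
rsa-miRn-28	GGUCUUUGGGAGUUGGAUUAUCAUC	0	856	0.0100	43.7801	12.10	1.31E-244	**	up-regulated
rsa-miRn-44	CGGUGGUGGAGGUGGAGGCGG	0	46	0.0100	2.3527	7.88	8.12E-14	**	up-regulated
rsa-miRn-45	UCAGCCGAGGUUCCAUUACCAC	0	206	0.0100	10.5359	10.04	2.09E-59	**	up-regulated
rsa-miRn-46	UGUUUUGUGCGUGAAUCUAAUU	0	48	0.0100	2.4550	7.94	2.18E-14	**	up-regulated
rsa-miRn-47	CGAAGUGACUUAUAAUGAUCU	0	32	0.0100	1.6366	7.35	7.91E-10	**	up-regulated
rsa-miRn-54	AGGAUUGAGUCUAGAAGCAUA	0	125	0.0100	6.3931	9.32	2.51E-36	**	up-regulated
rsa-miRn-55	UGGAUACAGUGAUGAUGACGAU	0	20	0.0100	1.0229	6.68	2.08E-06	**	up-regulated
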