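rank	chrom	pos	beta_coef	p	fdr	gene	prior_evidence
1	chr12	105478501	2.488	7.11e-11	1.80e-05	ALDH1L2	0
2	chr17	27052829	2.717	8.37e-09	6.20e-04	TLCD1	0
3	chr19	658314	0.319	1.17e-08	6.20e-04	RNF126	0
4	chr5	150027611	0.248	1.21e-08	6.20e-04	SYNPO	0
5	chr19	59073819	0.308	1.23e-08	6.20e-04	MZF1	1
6	chr7	157670224	0.228	1.55e-08	6.52e-04	PTPRN2	1
7	chr17	27052816	2.723	2.26e-08	7.92e-04	TLCD1	0
8	chr8	26148178	-1.772	2.72e-08	7.92e-04	PPP2R2A	0
9	chr19	59073806	0.261	3.03e-08	7.92e-04	MZF1	1
10	chr5	150027616	0.240	3.14e-08	7.92e-04	SYNPO	0
11	chr17	27052798	2.778	3.53e-08	8.11e-04	TLCD1	0
12	chr17	27052771	2.780	9.88e-08	2.08e-03	TLCD1	0
13	chr5	1233035	0.221	1.40e-07	2.70e-03	SLC6A18	1
14	chr5	1233066	0.181	1.61e-07	2.70e-03	SLC6A18	1
15	chr5	1233041	0.216	1.65e-07	2.70e-03	SLC6A18	1
16	chr5	1233045	0.210	1.71e-07	2.70e-03	SLC6A18	1
17	chr19	59073831	0.338	1.93e-07	2.87e-03	MZF1	1
18	chr9	119332867	0.324	2.44e-07	3.43e-03	ASTN2	1
19	chr9	119332835	0.306	3.30e-07	4.39e-03	ASTN2	1
20	chr7	157670239	0.200	4.07e-07	5.02e-03	PTPRN2	1
21	chr9	133911755	0.123	4.18e-07	5.02e-03	LAMC3	0
22	chr22	37298168	-2.138	4.52e-07	5.19e-03	IQCA1	0
23	chr22	37298161	-2.126	4.76e-07	5.23e-03	IQCA1	0
24	chr3	129059046	-2.528	5.34e-07	5.62e-03	MARK2P19	0
25	chr5	29364034	0.232	7.16e-07	7.05e-03	LINC02064	0
26	chr10	126490028	0.177	7.26e-07	7.05e-03	FAM175B	0
27	chr9	140033560	-0.277	8.28e-07	7.44e-03	GRIN1	1
28	chr18	14458789	-0.513	8.52e-07	7.44e-03	LONRF2P1	0
29	chr5	1233018	0.225	8.73e-07	7.44e-03	SLC6A18	1
30	chr11	72352936	0.232	8.84e-07	7.44e-03	PDE2A	1
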