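rank	chrom	pos	gene	m2f_self_change	m2f_p_self	m2f_cotwin_change	m2f_p_cotwin	m2f_ratio	f2m_self_change	f2m_p_self	f2m_cotwin_change	f2m_p_cotwin	f2m_ratio	flag_meth_to_fpg	flag_fpg_to_meth
1	chr12	105478501	ALDH1L2	0.016	4.63e-10	0.018	2.89e-10	1.065	-0.500	3.13e-01	-0.645	2.10e-01	1.290	0	0
2	chr17	27052829	TLCD1	0.017	2.03e-06	0.024	3.94e-05	1.421	-0.329	5.35e-01	-1.059	1.90e-02	3.218	0	1
3	chr19	658314	RNF126	0.046	1.40e-03	0.068	1.86e-06	1.472	-0.023	6.84e-01	-0.170	1.56e-01	7.489	0	0
4	chr5	150027611	SYNPO	0.082	1.23e-03	0.105	2.20e-03	1.283	-0.024	6.25e-01	-0.049	2.60e-01	2.090	0	0
5	chr19	59073819	MZF1	0.029	3.96e-01	0.151	9.44e-03	5.230	0.018	7.19e-01	-0.114	7.82e-02	-6.429	1	0
6	chr7	157670224	PTPRN2	0.077	3.46e-06	0.150	2.03e-09	1.931	0.001	9.81e-01	-0.072	1.12e-01	-71.878	1	0
7	chr17	27052816	TLCD1	0.016	7.29e-05	0.023	5.30e-04	1.449	-0.366	4.68e-01	-1.077	1.80e-02	2.945	0	1
8	chr8	26148178	PPP2R2A	-0.017	7.86e-05	-0.011	2.21e-03	0.618	0.630	1.23e-01	0.133	7.52e-01	0.212	0	0
9	chr19	59073806	MZF1	0.022	5.99e-01	0.112	4.71e-02	5.141	0.010	8.42e-01	-0.080	1.76e-01	-7.954	1	0
10	chr5	150027616	SYNPO	0.075	3.24e-03	0.095	4.41e-03	1.257	-0.023	6.43e-01	-0.044	3.23e-01	1.936	0	0
11	chr17	27052798	TLCD1	0.014	6.90e-04	0.019	2.95e-03	1.345	-0.448	3.91e-01	-0.963	4.57e-02	2.149	0	1
12	chr17	27052771	TLCD1	0.013	5.05e-03	0.015	1.54e-02	1.159	-0.568	3.03e-01	-0.797	1.41e-01	1.404	0	0
13	chr5	1233035	SLC6A18	0.140	7.45e-09	0.253	1.90e-09	1.808	0.005	8.90e-01	-0.091	1.38e-02	-18.774	1	1
14	chr5	1233066	SLC6A18	0.091	4.87e-06	0.177	2.09e-10	1.950	0.003	9.41e-01	-0.070	3.82e-02	-25.124	1	1
15	chr5	1233041	SLC6A18	0.134	8.86e-08	0.250	9.29e-09	1.862	0.008	8.17e-01	-0.093	1.18e-02	-11.256	1	1
16	chr5	1233045	SLC6A18	0.134	1.61e-07	0.249	1.14e-08	1.867	0.009	8.00e-01	-0.092	1.09e-02	-10.206	1	1
17	chr19	59073831	MZF1	0.025	4.45e-01	0.150	4.51e-03	6.074	0.024	6.57e-01	-0.130	8.19e-02	-5.416	1	0
18	chr9	119332867	ASTN2	0.154	2.04e-06	0.204	9.23e-08	1.331	-0.044	4.75e-01	-0.159	3.81e-03	3.636	0	1
19	chr9	119332835	ASTN2	0.091	1.65e-03	0.129	1.24e-05	1.425	-0.047	4.56e-01	-0.121	3.26e-02	2.598	0	1
20	chr7	157670239	PTPRN2	0.048	3.30e-03	0.162	5.31e-09	3.402	0.019	6.17e-01	-0.070	1.01e-01	-3.636	1	0
21	chr9	133911755	LAMC3	-0.030	5.49e-01	0.088	1.59e-01	-2.905	0.018	6.28e-01	-0.029	3.65e-01	-1.556	0	0
22	chr22	37298168	IQCA1	-0.016	1.05e-06	-0.026	2.19e-07	1.626	0.0001	1.00e+00	1.064	1.11e-02	7362.729	1	1
23	chr22	37298161	IQCA1	-0.016	1.11e-06	-0.026	2.24e-07	1.628	-0.003	9.95e-01	1.064	1.13e-02	-407.723	1	1
24	chr3	129059046	NA	-0.001	9.16e-01	-0.022	6.60e-03	41.613	-0.326	4.63e-01	0.935	5.72e-02	-2.869	1	0
25	chr5	29364034	LINC02064	0.044	3.14e-02	0.062	2.76e-03	1.419	-0.030	6.24e-01	-0.146	2.55e-01	4.921	0	0
26	chr10	126490028	FAM175B	-0.036	6.57e-01	0.209	9.03e-02	-5.886	0.010	7.41e-01	-0.028	4.45e-01	-2.713	0	0
27	chr9	140033560	GRIN1	0.029	2.49e-01	-0.047	4.72e-02	-1.618	-0.055	2.76e-01	0.064	1.29e-01	-1.165	1	0
28	chr18	14458789	LONRF2P1	-0.001	9.69e-01	-0.023	3.46e-01	18.309	-0.027	8.78e-01	0.121	3.42e-01	-4.420	0	0
29	chr5	1233018	SLC6A18	0.099	3.60e-04	0.193	3.06e-06	1.951	0.0003	9.93e-01	-0.078	6.70e-02	-223.473	1	0
30	chr11	72352936	PDE2A	0.143	1.95e-06	0.253	5.51e-10	1.770	-0.006	8.45e-01	-0.088	4.89e-03	14.239	1	1
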