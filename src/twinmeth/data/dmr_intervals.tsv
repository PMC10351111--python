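dmr_id	chrom	start	end	n_cpgs	slk_p	gene
1	chr17	27052679	27052830	6	3.76e-09	TLCD1
2	chr13	52769630	52769786	11	2.36e-08	MRPS31P5
3	chr18	14458531	14458993	25	2.78e-07	CXADRP3
4	chr11	1985750	1985907	10	1.36e-07	MRPL23
5	chr11	1989899	1991115	33	2.42e-06	AK126380
6	chr5	29364017	29364153	11	3.46e-07	NA
7	chr7	157670041	157670346	15	1.07e-06	PTPRN2
8	chr22	38723759	38724067	13	3.11e-06	CSNK1E
9	chr17	35017806	35017947	11	1.82e-06	NA
10	chr1	155790779	155790915	11	2.43e-06	GON4L
11	chr18	74154023	74154636	30	1.25e-05	ZNF516
12	chr16	33509364	33509939	41	1.27e-05	NA
13	chr1	10718376	10718662	12	8.32e-06	CASZ1
14	chr11	396866	397176	17	9.04e-06	PKP3
15	chr1	3111455	3111772	20	1.02e-05	PRDM16
16	chr1	180922670	180923856	41	4.87e-05	AK056657
17	chr17	36413806	36413942	12	5.79e-06	LOC440434
18	chr5	150027514	150027745	10	1.43e-05	SYNPO
19	chr17	20658746	20658885	11	8.99e-06	NA
20	chr18	73176	73654	32	4.12e-05	TUBB8B
21	chr1	53904769	53904934	15	1.55e-05	SLC25A3P1
22	chr4	30724012	30724138	16	1.21e-05	PCDH7
23	chr7	15725475	15725592	13	1.21e-05	MEOX2
24	chr16	86587026	86587188	8	1.70e-05	MTHFSD
25	chr10	126489968	126490164	9	2.19e-05	FAM175B
26	chr14	37667220	37667455	16	2.91e-05	MIPOL1
27	chr17	20747104	20747489	38	5.03e-05	BC067347
28	chr7	56439560	56439713	11	2.06e-05	NA
29	chr9	44118236	44118478	21	3.85e-05	NA
30	chr1	30758193	30758450	15	4.50e-05	NA
31	chr19	52996089	52996973	37	1.70e-04	ZNF578
32	chr19	48183202	48184154	68	1.88e-04	GLTSCR1
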