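locus	linkage_group	gene_id	portion_start	portion_end	alignment_length	rate_e9	gc_percent	pi_sites	pi_percent	exon_percent	ci	ri
1	L1	Medtr1g046610.1	961	3210	2368	5.25	28.5	153	6.46	24.22	0.97	0.93
2	L1	Medtr1g046590.1	2198	4140	2103	3.31	28.4	102	4.85	35.77	0.96	0.89
3	L1	Medtr1g046550.2	2881	5641	2883	2.62	33.6	152	5.27	37.12	0.96	0.91
4	L1	Medtr1g046580.1	76	2068	2394	6.10	34.2	133	5.56	35.22	0.95	0.83
5	L2	Medtr2g038160.1	1450	3600	2437	3.18	30.6	143	5.87	34.77	0.98	0.97
6	L2	Medtr2g038230.1	8	2737	3168	3.97	35.4	177	5.59	46.81	0.92	0.77
7	L2	Medtr2g038270.1	2448	4790	2445	2.68	32.7	120	4.89	35.08	0.99	0.97
8	L3	Medtr3g079820.1	1166	3496	2518	3.85	34.1	150	5.96	41.06	0.98	0.95
9	L3	Medtr3g079830.1	2122	4386	2366	3.16	36.4	141	5.96	37.09	0.97	0.94
10	L3	Medtr3g079840.1	4606	7039	2630	3.50	30.5	172	6.54	35.25	0.96	0.91
11	L4	Medtr4g092600.1	3041	5760	3048	4.01	33.5	187	6.14	32.35	0.98	0.96
12	L4	Medtr4g092630.3	1601	3887	2406	3.71	34.2	197	8.19	49.80	0.96	0.93
13	L4	Medtr4g092670.1	401	2877	2583	3.45	34.7	172	6.66	20.39	0.97	0.94
14	L5	Medtr5g033490.1	1505	4516	3158	3.24	34.6	190	6.02	47.01	0.95	0.89
15	L6	Medtr6g017950.1	935	3057	2472	5.14	34.3	189	7.65	33.25	0.95	0.86
16	L6	Medtr6g017970.1	5094	7760	2807	3.64	31.8	169	6.02	28.31	0.95	0.89
17	L7	Medtr7g064560.1	128	2882	2896	3.92	33.7	140	4.83	37.35	0.95	0.83
18	L7	Medtr7g064580.1	539	2753	2450	5.30	36	170	6.94	38.19	0.94	0.84
19	L8	Medtr8g083970.1	4729	7255	2665	1.90	33	93	3.49	35.77	0.98	0.95
20	L8	Medtr8g084020.1	2881	5420	3068	3.39	31.5	105	3.42	26.93	0.95	0.82
21	L8	Medtr8g084050.1	1423	3498	2236	3.18	32.2	130	5.81	34.10	0.97	0.93
22	L9	Medtr3g010000.1	2641	4815	2406	3.72	27.4	81	3.37	42.25	0.94	0.81
23	L9	Medtr3g009920.1	1681	4302	2839	4.83	31.7	208	7.33	40.20	0.96	0.89
24	L10	Medtr5g091180.1	401	3043	3037	4.31	28	101	3.33	39.88	0.98	0.92
25	L10	Medtr5g091210.1	1422	3771	2655	4.83	34.4	203	7.65	39.66	0.95	0.89
26	L10	Medtr5g091250.1	131	2249	2284	3.74	30.3	119	5.21	22.09	0.97	0.91
27	L11	Medtr6g083920.1	1	2318	2384	3.05	36.8	149	6.25	66.78	0.96	0.91
28	L11	Medtr6g083950.1	1841	4187	2657	4.69	33.5	168	6.32	31.57	0.95	0.88
29	L12	Medtr4g114440.1	1024	2897	1937	2.72	36.3	119	6.14	55.18	0.97	0.95
30	L12	Medtr4g114500.1	1281	3680	2482	4.00	34.9	207	8.34	37.00	0.94	0.88
31	L13	Medtr7g088900.1	1410	3844	2478	2.02	35.8	104	4.20	41.85	0.94	0.83
32	L13	Medtr7g088910.1	858	2983	2161	3.49	33.9	148	6.85	33.11	0.96	0.92
33	L13	Medtr7g088950.1	7521	9840	2465	2.44	33.7	95	3.85	40.22	0.96	0.86
34	L14	Medtr1g120740.1	3525	6095	2754	3.49	34.2	168	6.10	49.09	0.95	0.86
35	L14	Medtr1g120720.1	1841	3553	1821	3.51	32	105	5.77	32.69	0.97	0.94
36	L14	Medtr1g120640.1	2177	4419	2341	2.44	31.2	98	4.19	33.35	0.94	0.83
37	L15	Medtr2g122490.1	4793	6770	2056	2.78	32.6	101	4.91	28.72	0.97	0.92
38	L15	Medtr2g122410.1	4081	6431	2430	2.83	31.5	142	5.84	28.63	0.95	0.90
39	L15	Medtr2g122350.1	3766	5696	1998	3.26	31.9	135	6.76	36.82	0.97	0.93
40	L16	Medtr7g005780.1	1197	3112	2076	3.75	33.5	122	5.88	46.92	0.95	0.88
41	L16	Medtr7g005790.1	1231	3476	2367	4.73	34.1	113	4.77	25.20	0.94	0.76
42	L17	Medtr8g025590.1	1085	3065	2042	3.22	31.8	123	6.02	38.31	0.99	0.97
43	L17	Medtr8g025650.1	603	2372	1806	3.73	35.1	132	7.31	36.33	0.97	0.96
44	L18	Medtr2g046770.1	1521	3997	2830	5.70	34.2	254	8.98	39.89	0.95	0.90
45	L18	Medtr2g046700.1	2732	5144	2795	4.11	34.9	190	6.81	36.51	0.95	0.87
46	L18	Medtr2g046560.1	1321	3086	1833	2.24	33.1	93	5.07	29.73	0.99	0.98
47	L19	Medtr4g080820.1	641	2957	2412	3.72	35.4	144	5.97	48.25	0.97	0.94
48	L20	Medtr3g113790.1	8490	10497	2137	2.23	33.6	94	4.40	33.62	1.00	0.99
49	L20	Medtr3g113840.1	5320	7261	1980	4.47	34.5	101	5.10	36.20	0.96	0.91
50	L20	Medtr3g113960.1	2051	3847	1886	2.01	32.2	75	3.98	37.34	0.97	0.93
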