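graph	ABC	R	M1	M2	ReZ1	ReZ2	SO	SS	BMG	GBM	GA	mM2
G1	15.99	5.42	324	918	10.95	79.54	231.14	47.82	219.09	3.91	28.72	1.05
G2	9.04	3.16	170	454	6.43	41.34	121.81	25.6	116.32	2.24	15.76	0.64
G3	12.83	4.45	250	695	8.99	61.39	178.32	37.38	170.32	3.17	22.79	0.9
G4	12.1	4.11	254	752	8.38	61.81	181.95	36.59	169.99	2.93	21.66	0.83
G5	18.31	6.26	362	1004	12.66	88.86	258.26	53.93	246	4.5	32.68	1.22
G6	11.19	3.93	220	630	7.96	53.63	157.47	32.48	149.13	2.78	19.75	0.82
G7	14.35	4.97	300	911	10.09	72.97	214.96	43.11	200.69	3.52	25.64	1.03
G8	13	4.68	242	652	9.45	59.3	172.8	36.7	166.25	3.27	22.77	1.03
G9	16.74	5.73	326	888	11.63	79.67	233.05	48.71	221.93	4.11	29.62	1.12
G10	12.24	4	292	968	8.14	71	209.26	40.01	190.69	2.9	22.65	0.76
G11	13.53	4.5	292	875	9.06	72.06	207.79	42.22	195.42	3.27	24.82	0.85
G12	6.11	2.11	122	348	4.27	29.87	87.15	18.01	82.61	1.5	10.88	0.43
G13	19.25	6.54	390	1107	13.16	96.15	277.66	57.77	264.14	4.72	34.76	1.26
G14	12.44	4.14	272	833	8.36	66.91	193.86	38.96	181.29	3.01	22.81	0.79
G15	11.81	4.2	230	657	8.53	55.95	164.8	33.96	156.05	2.94	20.7	0.91
G16	15.58	5.35	306	845	10.84	74.89	218.62	45.6	208.01	3.83	27.69	1.06
G17	20.23	6.81	422	1224	13.78	103.87	300.69	61.69	284.02	4.92	36.67	1.32
G18	14.35	4.97	300	911	10.09	72.97	214.96	43.11	200.69	3.52	25.64	1.03
G19	14.86	5.04	300	845	10.16	73.91	213.66	44.51	203.3	3.64	26.8	0.97
G20	12.97	4.46	296	982	9.03	72.03	212.04	41	194.65	3.15	23.69	0.95
G21	10.62	3.78	228	741	7.84	54.18	165.12	31.47	150.26	2.59	18.45	0.88
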