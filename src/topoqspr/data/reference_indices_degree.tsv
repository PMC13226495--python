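graph	ABC	R	M1	M2	ReZ1	ReZ2	SO	SS	BMG	GBM	GA	mM2
G1	20.56	12.7	138	162	26	33.3	99.23	30.97	126.95	6.66	28.45	5.69
G2	12.04	7.29	78	85	16	16.98	58.5	16.36	71.03	3.62	14.84	3.43
G3	16.36	10.24	108	125	21	26	77.74	24.36	99.99	5.32	22.53	4.67
G4	15.57	9.7	106	127	20	25.47	76.37	23.53	97.04	5.03	21.49	4.47
G5	23.5	14.6	156	181	30	37.45	112.43	35.02	143.98	7.61	32.27	6.61
G6	14.53	9.01	96	110	19	22.13	70.4	20.91	87.95	4.59	19.15	4.19
G7	18.55	11.55	126	150	24	29.71	91.54	27.62	114.93	5.94	25.18	5.36
G8	16.64	10.5	108	121	22	25.08	78.93	23.89	99.94	5.34	22.15	4.94
G9	21.6	13.44	142	163	28	33.55	103.06	31.57	131.08	6.9	29.05	6.19
G10	16.13	9.74	116	146	20	27.81	83.66	25.14	103.86	5.15	22.49	4.33
G11	17.73	10.7	122	146	22	29.3	87.91	26.97	110.95	5.66	24.45	4.69
G12	7.81	4.88	52	61	10	12.55	37.38	11.7	48	2.54	10.79	2.22
G13	24.7	15.26	166	195	31	40.35	118.97	37.48	152.87	8.06	34.5	6.78
G14	16.17	9.83	112	136	20	27.25	80.23	24.94	101.95	5.22	22.66	4.31
G15	15.12	9.55	100	115	20	23.25	73.08	21.95	91.94	4.85	20.21	4.53
G16	20.21	12.44	134	153	26	31.27	97.75	29.46	122.89	6.42	27.02	5.67
G17	26.18	16.1	178	211	33	42.87	128.12	39.68	162.92	8.45	36.25	7.22
G18	18.55	11.55	126	150	24	29.71	91.54	27.62	114.93	5.94	25.18	5.36
G19	19.08	11.79	128	150	24	31.05	91.82	28.88	117.91	6.21	26.58	5.25
G20	16.69	10.37	118	148	21	28.76	84.46	26.12	106.86	5.46	23.71	4.69
G21	13.32	8.7	92	114	18	21.93	66.53	20.2	84	4.38	18.49	4.32
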