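graph	drug	MW	HAC	CO	BP	EV	FP	MR	PO	MV
G1	Trazodone	371.9	26	611	528.5	80.3	273.4	104.2	41.3	278.8
G2	Bupropion	239.74	16	247	334.8	57.8	156.3	67.9	26.9	224.7
G3	Vortioxetine	298.4	21	316	424.8	67.9	210.7	92.7	36.8	256.5
G4	Sertraline	306.2	20	322	416.3	67	205.6	85.8	34	243.9
G5	Aripiprazole	448.4	30	559	646.2	95.3	344.6	120.3	47.7	355
G6	Desvenlafaxine	263.37	19	266	403.8	69.1	193.2	77.8	30.9	236.1
G7	Citalopram	324.4	24	466	428.3	68.3	212.8	92.1	36.5	272.6
G8	Fluoxetine	309.33	22	308	395.1	64.5	192.8	79.9	31.7	266.7
G9	Cariprazine	427.4	28	491	600.1	89.3	316.7	117.2	46.4	344.5
G10	Dextromethorphan	271.4	20	370	394.9	64.5	116.2	81.8	32.4	243.8
G11	Olanzapine	312.4	22	432	476	74	241.7	92.2	36.5	236
G12	Tranylcypromine	133.19	10	116	218.3	45.5	90.8	41.8	16.6	125
G13	Brexpiprazole	433.6	31	636	675.2	99.1	362.1	126.3	50.1	348
G14	Mirtazapine	265.35	20	345	432.4	68.8	215.3	80.7	32	216.6
G15	Venlafaxine	277.4	20	279	397.6	68.3	194.2	82.6	32.8	261.7
G16	Gepirone	359.5	26	476	562.3	84.5	293.8	99	39.3	314.7
G17	Vilazodone	441.5	33	729	745.1	108.6	404.4	128.7	51	328.8
G18	Escitalopram	324.4	24	466	428.3	68.3	212.8	92.1	36.5	272.6
G19	Paroxetine	329.4	24	402	451.7	71.1	227	87.9	34.9	271.5
G20	Maprotiline	277.4	21	339	399.6	65	187.7	87.8	34.8	256.7
G21	Levomilnacipran	246.35	18	295	393	64.3	191.5	73.2	29	228.6
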