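graph	(1,2)	(1,3)	(1,4)	(2,2)	(2,3)	(2,4)	(3,3)	(3,4)
G1	0	2	0	9	14	0	4	0
G2	0	3	3	2	5	1	2	0
G3	0	2	0	8	10	0	3	0
G4	1	2	0	5	9	0	5	0
G5	0	3	0	10	16	0	4	0
G6	0	3	1	6	6	2	1	1
G7	1	3	0	6	11	2	1	2
G8	1	0	3	8	9	0	1	1
G9	0	5	0	7	14	0	4	0
G10	1	1	0	5	9	2	3	2
G11	0	2	0	5	14	0	4	0
G12	0	1	0	4	4	0	2	0
G13	0	1	0	12	18	0	4	0
G14	0	1	0	7	10	0	5	0
G15	1	2	1	6	7	2	1	1
G16	0	2	2	9	10	2	3	0
G17	1	2	0	8	21	0	5	0
G18	1	3	0	6	11	2	1	2
G19	0	1	0	9	14	0	3	0
G20	1	0	0	10	5	2	4	2
G21	3	1	0	4	6	1	1	3
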