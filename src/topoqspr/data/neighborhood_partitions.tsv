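graph	(2,3)	(2,4)	(3,4)	(3,5)	(3,6)	(3,7)	(3,8)	(4,4)	(4,5)	(4,6)	(4,7)	(4,8)	(5,5)	(5,6)	(5,7)	(5,8)	(5,9)	(6,6)	(6,7)	(6,8)	(6,9)	(6,10)	(7,7)	(7,8)	(7,9)	(7,11)	(8,8)	(8,9)	(8,10)	(8,11)	(9,10)
G1	0	0	0	1	0	1	0	1	6	0	0	0	3	4	5	1	0	0	3	0	0	0	2	2	0	0	0	0	0	0	0
G2	0	0	0	1	1	1	0	0	5	0	0	0	1	1	2	0	0	0	3	0	0	0	1	0	0	0	0	0	0	0	0
G3	0	0	0	1	1	0	0	3	4	0	0	0	2	1	4	1	0	1	3	0	0	0	0	2	0	0	0	0	0	0	0
G4	0	1	0	0	2	0	0	1	2	0	1	0	2	1	2	3	0	2	1	0	0	0	0	2	0	0	2	0	0	0	0
G5	0	0	0	1	1	1	0	2	4	0	0	0	5	7	4	1	0	1	3	0	0	0	1	2	0	0	0	0	0	0	0
G6	0	0	2	1	0	0	0	2	0	3	0	1	4	0	2	0	0	0	0	2	1	0	0	0	1	0	0	1	0	0	0
G7	0	1	2	1	0	0	0	0	2	2	0	0	5	2	1	2	1	1	1	0	0	2	0	0	1	0	0	0	1	0	1
G8	1	0	1	0	0	0	0	2	3	3	0	0	2	2	3	2	0	1	1	1	0	0	1	0	0	0	0	0	0	0	0
G9	0	0	0	2	2	1	0	0	2	0	0	0	5	10	2	1	0	2	1	0	0	0	0	2	0	0	0	0	0	0	0
G10	0	1	0	0	1	0	0	1	1	2	0	0	1	3	1	0	1	1	1	2	1	2	0	0	1	0	0	1	0	0	2
G11	0	0	0	2	0	0	0	1	2	0	0	0	4	2	4	0	0	0	4	2	0	0	1	2	0	0	1	0	0	0	0
G12	0	0	0	0	1	0	0	2	2	0	0	0	0	0	2	0	0	1	0	2	0	0	0	1	0	0	0	0	0	0	0
G13	0	0	0	1	0	0	0	2	6	0	0	0	5	6	6	2	0	1	2	0	0	0	1	2	0	0	1	0	0	0	0
G14	0	0	0	1	0	0	0	2	4	0	0	0	2	1	2	3	0	0	2	1	0	0	0	2	0	0	3	0	0	0	0
G15	0	1	2	0	0	0	0	2	0	4	0	1	2	2	2	0	0	0	0	2	1	0	0	0	1	0	0	1	0	0	0
G16	0	0	0	0	2	0	0	3	4	2	0	0	2	3	4	1	0	0	4	2	0	0	1	0	0	0	0	0	0	0	0
G17	0	1	0	2	0	0	0	1	2	1	0	0	5	4	9	0	0	1	6	1	0	0	2	2	0	0	0	0	0	0	0
G18	0	1	2	1	0	0	0	0	2	2	0	0	5	2	1	2	1	1	1	0	0	2	0	0	1	0	0	0	1	0	1
G19	0	0	0	1	0	0	0	1	4	0	0	0	6	2	7	1	0	1	1	0	0	0	1	2	0	0	0	0	0	0	0
G20	1	0	1	0	0	0	0	3	4	1	0	0	0	1	0	3	2	0	0	0	0	2	0	0	0	0	2	2	0	0	2
G21	0	3	0	0	0	0	1	2	2	0	2	1	0	0	0	2	0	0	0	0	0	0	0	2	0	1	0	0	0	3	0
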