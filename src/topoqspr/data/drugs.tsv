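graph	drug
G1	Trazodone
G2	Bupropion
G3	Vortioxetine
G4	Sertraline
G5	Aripiprazole
G6	Desvenlafaxine
G7	Citalopram
G8	Fluoxetine
G9	Cariprazine
G10	Dextromethorphan
G11	Olanzapine
G12	Tranylcypromine
G13	Brexpiprazole
G14	Mirtazapine
G15	Venlafaxine
G16	Gepirone
G17	Vilazodone
G18	Escitalopram
G19	Paroxetine
G20	Maprotiline
G21	Levomilnacipran
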