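index	MW	HAC	CO	BP	EV	FP	MR	PO	MV
ABC	0.9736	0.9969	0.957	0.9713	0.9649	0.9481	0.977	0.9773	0.9323
R	0.9758	0.9976	0.9435	0.9656	0.9607	0.951	0.9732	0.9736	0.9463
M1	0.914	0.9589	0.9596	0.9381	0.9289	0.8879	0.9456	0.9454	0.8612
M2	0.7935	0.861	0.8931	0.8285	0.8146	0.748	0.8525	0.8518	0.7504
ReZ1	0.9764	0.9977	0.944	0.9662	0.9613	0.9511	0.9737	0.9741	0.9485
ReZ2	0.9151	0.9596	0.9595	0.9394	0.9304	0.8906	0.9462	0.9461	0.8595
SO	0.9131	0.9584	0.9594	0.9372	0.928	0.8864	0.9451	0.9448	0.8618
SS	0.9452	0.9803	0.9646	0.9592	0.9512	0.9211	0.9646	0.9646	0.8924
BMG	0.9305	0.971	0.9634	0.9498	0.9412	0.9056	0.9564	0.9563	0.8783
GBM	0.9764	0.9978	0.9494	0.9692	0.9636	0.9514	0.9756	0.976	0.9396
GA	0.963	0.9912	0.9612	0.9677	0.9607	0.9389	0.9728	0.973	0.9145
mM2	0.9417	0.9694	0.896	0.9224	0.9209	0.9203	0.9346	0.9351	0.9411
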