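index	MW	HAC	CO	BP	EV	FP	MR	PO	MV
ABC	0.9734	0.9968	0.9534	0.9604	0.9473	0.9312	0.977	0.9773	0.9272
R	0.9758	0.9976	0.9385	0.9531	0.9416	0.9335	0.9732	0.9736	0.9424
M1	0.9139	0.9585	0.9511	0.9218	0.904	0.8633	0.9451	0.9449	0.8581
M2	0.7933	0.8607	0.8828	0.8161	0.7945	0.7328	0.8522	0.8515	0.7447
ReZ1	0.9764	0.9977	0.9386	0.9533	0.9416	0.933	0.9736	0.974	0.9448
ReZ2	0.9151	0.9594	0.9521	0.9242	0.9066	0.8671	0.9459	0.9458	0.8558
SO	0.9131	0.9578	0.9504	0.9204	0.9024	0.8613	0.9444	0.9442	0.859
SS	0.9451	0.9803	0.9594	0.9462	0.9304	0.9003	0.9645	0.9646	0.888
BMG	0.9305	0.9708	0.9564	0.9349	0.918	0.8825	0.9561	0.956	0.8748
GBM	0.9762	0.9977	0.9457	0.9582	0.9462	0.9353	0.9756	0.976	0.9347
GA	0.9628	0.9912	0.9573	0.9564	0.9423	0.9209	0.9728	0.973	0.9093
mM2	0.9395	0.9667	0.8808	0.8994	0.89	0.892	0.9318	0.9323	0.9407
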