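index	MW	HAC	CO	BP	EV	FP	MR	PO	MV
ABC	0.9725	0.9962	0.9568	0.9609	0.9476	0.9279	0.9767	0.9769	0.9247
R	0.9756	0.9983	0.9511	0.9594	0.9466	0.9313	0.9775	0.9777	0.9338
M1	0.9518	0.9855	0.9612	0.9497	0.9344	0.9042	0.968	0.9681	0.9
M2	0.9139	0.9585	0.9511	0.9218	0.904	0.8633	0.9451	0.9449	0.8581
ReZ1	0.98128	1	0.9479	0.9601	0.948	0.9337	0.97767	0.9779	0.9457
ReZ2	0.9373	0.9742	0.9565	0.9413	0.925	0.8948	0.96	0.96	0.8766
SO	0.9567	0.9889	0.9616	0.9518	0.9369	0.9067	0.9699	0.9699	0.9091
SS	0.9514	0.984	0.9584	0.9503	0.9351	0.9092	0.9678	0.9679	0.8943
BMG	0.9583	0.9892	0.9604	0.9539	0.939	0.9128	0.9715	0.9716	0.9062
GBM	0.967	0.9935	0.9546	0.9576	0.9439	0.9257	0.9746	0.9748	0.9167
GA	0.9561	0.9866	0.9562	0.9527	0.9379	0.9158	0.9698	0.97	0.8998
mM2	0.977	0.9959	0.9358	0.9505	0.9388	0.9284	0.9721	0.9723	0.9509
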