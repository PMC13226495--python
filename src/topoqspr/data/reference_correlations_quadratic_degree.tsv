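index	MW	HAC	CO	BP	EV	FP	MR	PO	MV
ABC	0.9727	0.9963	0.9607	0.97239	0.966	0.9459	0.9767	0.9769	0.9301
R	0.9757	0.9983	0.9553	0.971	0.965	0.9489	0.9775	0.9777	0.9386
M1	0.9519	0.9855	0.9668	0.963	0.9554	0.9253	0.9681	0.9681	0.9047
M2	0.914	0.9589	0.9596	0.9381	0.9289	0.8879	0.9456	0.9454	0.8612
ReZ1	0.98131	1	0.9525	0.97236	0.9671	0.9519	0.9777	0.97794	0.9503
ReZ2	0.9373	0.9742	0.9618	0.9547	0.9463	0.916	0.9601	0.9601	0.8804
SO	0.9567	0.9889	0.9676	0.9655	0.9582	0.9283	0.97	0.97	0.9138
SS	0.9515	0.984	0.9629	0.9625	0.9547	0.9287	0.9679	0.968	0.8988
BMG	0.9583	0.9892	0.9652	0.9663	0.9589	0.9327	0.9716	0.9716	0.911
GBM	0.9672	0.9936	0.9583	0.9686	0.9618	0.943	0.9746	0.9748	0.9216
GA	0.9562	0.9866	0.9602	0.9642	0.9567	0.9342	0.9698	0.97	0.9043
mM2	0.9771	0.996	0.9422	0.9648	0.9601	0.9485	0.9724	0.9726	0.954
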