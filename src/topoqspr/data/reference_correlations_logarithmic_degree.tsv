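index	MW	HAC	CO	BP	EV	FP	MR	PO	MV
ABC	0.9556	0.9776	0.9184	0.9146	0.8948	0.8742	0.9587	0.9589	0.9274
R	0.9573	0.979	0.9128	0.9133	0.8941	0.8779	0.9586	0.9588	0.9346
M1	0.9334	0.964	0.9181	0.9008	0.8788	0.8484	0.9473	0.9473	0.9021
M2	0.8953	0.9356	0.905	0.8728	0.8485	0.8092	0.9227	0.9225	0.8597
ReZ1	0.9609	0.9783	0.9077	0.912	0.8936	0.8783	0.957	0.9572	0.945
ReZ2	0.9205	0.9552	0.9157	0.8946	0.8715	0.8412	0.9409	0.9408	0.8789
SO	0.9368	0.9655	0.9168	0.9012	0.8798	0.8493	0.9478	0.9478	0.9101
SS	0.9351	0.9658	0.9191	0.9043	0.8823	0.8558	0.9497	0.9498	0.8971
BMG	0.9406	0.9691	0.9193	0.9062	0.8847	0.858	0.9521	0.9521	0.9085
GBM	0.9509	0.9764	0.9176	0.9129	0.8926	0.8735	0.9575	0.9577	0.9192
GA	0.9403	0.9695	0.9185	0.9077	0.8863	0.8634	0.9525	0.9527	0.9025
mM2	0.9534	0.9716	0.8938	0.9012	0.8833	0.872	0.9488	0.949	0.9466
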