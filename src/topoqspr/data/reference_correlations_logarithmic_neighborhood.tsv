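index	MW	HAC	CO	BP	EV	FP	MR	PO	MV
ABC	0.9569	0.9793	0.9165	0.9156	0.896	0.879	0.9598	0.96	0.9296
R	0.9569	0.9779	0.9005	0.9077	0.89	0.8811	0.9541	0.9545	0.9418
M1	0.8953	0.9356	0.905	0.8728	0.8485	0.8092	0.9227	0.9225	0.8597
M2	0.7886	0.8474	0.8422	0.7818	0.7549	0.6995	0.839	0.8384	0.7574
ReZ1	0.9562	0.9767	0.8996	0.9068	0.889	0.8795	0.9534	0.9537	0.9432
ReZ2	0.898	0.9382	0.9076	0.8761	0.852	0.8135	0.9251	0.9249	0.8589
SO	0.8937	0.9342	0.9035	0.871	0.8465	0.8069	0.9213	0.921	0.8598
SS	0.9282	0.9607	0.9181	0.8989	0.8764	0.8461	0.9452	0.9452	0.8908
BMG	0.912	0.9488	0.9119	0.886	0.8625	0.8275	0.9345	0.9344	0.8763
GBM	0.9601	0.9808	0.91	0.9145	0.8962	0.8844	0.959	0.9593	0.9368
GA	0.9472	0.9739	0.9196	0.9112	0.8905	0.8683	0.9558	0.956	0.9128
mM2	0.9127	0.9377	0.8371	0.8507	0.8358	0.8366	0.9061	0.9065	0.9303
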