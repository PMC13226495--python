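file	sha256
degree_partitions.tsv	c4a69048849628c68fd837028e2fc4cbf269fc2cdafae2897c9574027cabbfc5
drugs.tsv	287d593a7b1320eac2673826d1f6c6fad607f709afb3c74a469d4c3ebf92d77a
external_properties.tsv	234c05347dde8d0136b513a2a007f7f9e5300331bc1acbc06124eba0480c89d3
graphs/duloxetine.edges	bd9fa9305d38755caf98a4b2ac0701b73f1b43a874600a6b34681b4d03fd535e
graphs/esketamine.edges	7c0373fe0c79a1a58cfa671da9c5e7c39a2d38d6365cc049f0766444610d791f
graphs/tranylcypromine.edges	29ead4ad7f68670a71aae6c658c04347ddc81560c2ec724135a9103d3dfdfabc
neighborhood_partitions.tsv	66cc14dd0f4dea09abf033c8cd0a0e71b55a678361615948c784943bc1236ece
properties.tsv	6fd451d046fee8c84f0e14ec33c45d1630132fa109620469f6f750a7623abfd3
reference_correlations_linear_degree.tsv	e65cc59977f06f7241b0246f6bfaade2560561df1a8f94aaf533446df6060cc2
reference_correlations_linear_neighborhood.tsv	826fa3ce506bca8ae388d24f2198005add154ee89178f41aa44d6e3e0b0aa3b5
reference_correlations_logarithmic_degree.tsv	5cc8ca46a3aba48d40f0f89cf250573de57f97a5c2f4ea2fd7fb3569e9fbb605
reference_correlations_logarithmic_neighborhood.tsv	c7b3423a4f18d60612226026f2139fbf8bf0ec60e3803cf791f3e6beb49ce7f6
reference_correlations_quadratic_degree.tsv	5991eecfaa290d127c8700e39650c7444801de51a759a7c1831f016dc6a65b53
reference_correlations_quadratic_neighborhood.tsv	fa5513483b4cfa91985d6a403479ef5b61fb920570158829c07b0f4b5f56ecf8
reference_indices_degree.tsv	b9ab95ea54a47fa1f43d856912755e3b61d7f7f6f5ac29084f0c9cfce8e734ed
reference_indices_neighborhood.tsv	9dfe07a9b4ac1316d91a0209fdea52a9da74c82545dd652da7ecfb6e51c87f6c
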