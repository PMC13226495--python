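graph	drug	MW	HAC
X1	Duloxetine	297.4	21
X2	Esketamine	237.72	16
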