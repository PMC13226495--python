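# Esketamine (2-(2-chlorophenyl)-2-(methylamino)cyclohexan-1-one),
# hydrogen-suppressed skeleton, hand-encoded from the drug's published
# chemical structure (external test compound).
# c1-c6 cyclohexanone ring (c1 carbonyl carbon); o7 carbonyl oxygen;
# c8-c13 chlorophenyl ring; cl14 chlorine; n15 amine; c16 N-methyl.
c1 c2
c2 c3
c3 c4
c4 c5
c5 c6
c6 c1
c1 o7
c2 c8
c8 c9
c9 c10
c10 c11
c11 c12
c12 c13
c13 c8
c9 cl14
c2 n15
n15 c16
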