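# Duloxetine, hydrogen-suppressed skeleton, hand-encoded from the drug's
# published chemical structure (external test compound; structure not part
# of the bundled 21-drug dataset).
# c1-c10 naphthalene; o11 aryl ether oxygen; c12 benzylic carbon;
# c13-c14 propyl chain; n15 secondary amine; c16 N-methyl;
# c17-c20 + s21 thiophene ring.
c1 c2
c2 c3
c3 c4
c4 c5
c5 c6
c6 c7
c7 c8
c8 c9
c9 c10
c10 c1
c5 c10
c1 o11
o11 c12
c12 c13
c13 c14
c14 n15
n15 c16
c12 c17
c17 c18
c18 c19
c19 c20
c20 s21
s21 c17
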