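# Tranylcypromine (2-phenylcyclopropan-1-amine), hydrogen-suppressed skeleton.
# c1-c6 benzene ring; c7 ring-attached cyclopropane carbon; c8 amine-bearing
# cyclopropane carbon; c9 cyclopropane CH2; n10 amine nitrogen.
c1 c2
c2 c3
c3 c4
c4 c5
c5 c6
c6 c1
c1 c7
c7 c8
c8 c9
c9 c7
c8 n10
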