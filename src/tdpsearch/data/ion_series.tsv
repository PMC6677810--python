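# Neutral monoisotopic fragment mass offsets relative to the bare residue sum of the
# fragment. z is the z-dot radical species observed in ETD/ECD.
series	terminus	offset
a	N	-27.994915
b	N	0.0
c	N	17.026549
x	C	43.989830
y	C	18.010565
z	C	1.991841
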