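phiETA3	1	43282
phiNM1	1	43128
phiNM2	1	43145
B236	1	43228
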