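85	1	44283
88	1	43231
92	1	42431
29	1	42802
187	1	39620
53	1	43883
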