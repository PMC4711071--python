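U2	75	45955
Alvin	75	45163
DD5	75	46027
BillKnuckles	75	45715
Perseus	75	47564
Dreamboat	75	44313
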