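U2	1	33000
Doom	1	33000
Alvin	1	33000
BXB1	1	33000
Solon	1	33000
Bethlehem	1	33000
DD5	1	33000
Pinto	1	33000
BillKnuckles	1	33000
KBG	1	33000
Lesedi	1	33000
Museum	1	33000
Violet	1	33000
Kugel	1	33000
MrGordo	1	33000
KSSJEB	1	33000
Switzer	1	33000
Perseus	1	33000
Dreamboat	1	33000
Seabiscuit	1	33000
Trouble	1	33000
BPBiebs31	1	33000
Wheeler	1	33000
Graduation	1	33000
JC27	1	33000
Thor	1	33000
Aeneas	1	33000
SarFire	1	33000
SkiPole	1	33000
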