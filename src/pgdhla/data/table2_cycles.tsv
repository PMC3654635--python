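row	cycle1	cycle2
Number of oocytes retrieved	20	25
MII oocytes	17	22
2-pronuclei zygotes	14	18
Embryos biopsied	11	17
Affected	2	8
Carriers	7	3
Noncarriers	2	6
HLA nonidentical	9	14
HLA-identical	2	3
HLA nonidentical and affected	1	7
HLA nonidentical and carriers	6	1
HLA nonidentical and noncarriers	2	6
HLA-identical and affected	1	1
HLA-identical and carriers	1	2
HLA-identical and noncarriers	0	0
Embryos transferred	1	1
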