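# SYNTHETIC reconstruction of the 13-cross design. Only 17H39 (E103 x PDLUC)
# and 17H57 (E103 x E111) are documented crosses; the remaining parent
# assignments were chosen so that every printed F1 marker call is
# Mendelian-consistent with the parental marker table.
hybrid	parent1	parent2
17H14	PDVIT	E7
17H25	E11	E20
17H36	E103	E42
17H37	E103	E36
17H39	E103	PDLUC
17H56	E55	E103
17H57	E103	E111
18H13	E42	LA3120
18H17	E109	E20
18H48	E11	E48
18H56	E11	LA2662
18H57	E109	E7
18H59	E42	E109
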