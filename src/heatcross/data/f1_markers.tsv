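genotype	Mi-1.2	Ph-3	Sw-5	Tm-2	Ty-3	Ve-1
17H14	RR	SS	SS	RS	RS	SS
17H25	RR	RS	SS	SS	SS	RS
17H36	RR	SS	SS	RS	SS	RS
17H37	RR	RS	SS	RS	SS	SS
17H39	RR	SS	SS	RS	RS	SS
17H56	RR	RS	SS	RS	RS	SS
17H57	RR	RS	SS	RS	SS	SS
18H13	RR	SS	SS	SS	SS	RS
18H17	RR	RS	SS	SS	SS	RS
18H48	RR	RR	SS	SS	SS	RS
18H56	RR	RS	SS	SS	SS	RS
18H57	RR	RS	SS	SS	SS	RS
18H59	RR	RS	SS	SS	SS	RR
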