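genotype	Mi-1.2	Ph-3	Sw-5	Tm-2	Ty-3	Ve-1
E7	RR	SS	SS	SS	SS	SS
E11	RR	RR	SS	SS	SS	RR
E20	RR	SS	SS	SS	SS	SS
E36	RR	RR	SS	SS	SS	SS
E42	RR	SS	SS	SS	SS	RR
E45	RR	RR	SS	SS	SS	SS
E48	RR	RR	SS	SS	SS	SS
E55	RR	RR	SS	SS	RR	SS
E103	RR	SS	SS	RR	SS	SS
E109	RR	RR	SS	SS	SS	RR
E111	RR	RR	SS	SS	SS	SS
LA2662	RR	SS	SS	SS	SS	SS
LA3120	RR	SS	SS	SS	SS	SS
PDLUC	RR	RR	SS	SS	RR	SS
PDVIT	RR	SS	SS	RR	RR	SS
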