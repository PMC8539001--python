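gene	mutated_genotypes	predicted_effect	protein_function
Solyc01g014520	E42	missense_variant	Receptor-like protein kinase
Solyc01g074010	E11, E42	missense_variant	Protein kinase domain
Solyc01g080880	E20, E42, PDVIT	missense_variant	Protein kinase domain
Solyc01g087200	E42, E55	missense_variant	Disease resistance protein
Solyc02g070000	E11, E36, E42, E55	missense_variant	Leucine-rich receptor-like protein kinase family protein
Solyc02g078780	PDVIT	missense_variant	Protein STRUBBELIG-RECEPTOR FAMILY 3
Solyc02g093100	E7, E11, E36, E42, E45, E48, E55, PDVIT	missense_variant	Leucine-rich repeat protein kinase family protein
Solyc04g007030	E11, E36, E42	missense_variant	Disease resistance protein
Solyc04g008650	E7, E11, E20, E36, E42, E45	missense_variant	Inactive leucine-rich repeat receptor-like serinethreonine-protein kinase
Solyc04g014400	E11, E36, E42, E55	missense_variant	LRR receptor-like serine/threonine-protein kinase GSO1
Solyc04g015130	E42, E55, PDVIT	missense_variant	Protein kinase G11A
Solyc04g049400	E42, E55, PDVIT	missense_variant	Protein kinase domain
Solyc04g054200	E42, E55, PDVIT	missense_variant	Leucine-rich receptor-like protein kinase family protein
Solyc04g057930	E11 (2), E42 (2), E55 (2), E109, PDVIT (2)	missense_variant	Pkinase domain-containing protein/Usp domain-containing protein
Solyc04g074270	E11 (3), PDVIT (3)	missense_variant	Outer arm dynein light chain 1
Solyc04g082510	E55 (2)	missense_variant; stop_gained	Protein kinase
Solyc04g082620	E55 (2)	missense_variant	Serine/threonine-protein kinase/endoribonuclease IRE1a
Solyc05g009740	E7, E11 (2), E20, E45, E109 (2)	missense_variant	Disease resistance protein
Solyc05g009800	E11, E109	missense_variant	Leucine-rich repeat receptor-like serine/threonine-protein kinase
Solyc05g013280	LA3120 (2)	missense_variant	Pseudomonas resistance
Solyc05g050700	E11, E36, E42, E109, PDVIT	missense_variant	Leucine-rich repeat protein
Solyc05g051050	E11, E36, E42, E109	missense_variant	Shaggy-related protein kinase theta
Solyc05g053010	E11, E109, PDVIT	missense_variant	Lectin receptor kinase
Solyc05g053930	E55	missense_variant	Protein kinase APK1B, chloroplastic
Solyc05g054340	E55, PDVIT	missense_variant	Plant resistance protein
Solyc06g036470	E55	missense_variant	G-type lectin S-receptor-like serine/threonine-protein kinase
Solyc06g060690	E11, E55, PDVIT	stop_gained	Protein kinase superfamily protein
Solyc06g068920	E7, E20, E36, E42, E48	stop_lost	Protein kinase domain
Solyc06g072340	E11, E36, E45, E55, E109	missense_variant	Protein kinase domain
Solyc07g007140	E11, E42, E48, E55, E109	missense_variant	MAP kinase kinase kinase 44
Solyc07g053010	E42, PDVIT	missense_variant	Disease resistance protein
Solyc07g053300	E42	missense_variant	ABC transporter G family member 10
Solyc07g053910	E55	missense_variant	Protein kinase domain
Solyc07g055670	E11, E42, E45, E48, E55, PDVIT	missense_variant	Lectin-domain receptor-like kinase
Solyc07g062040	E42, E55	stop_gained	Receptor-like serine/threonine-protein kinase
Solyc08g081210	E20, E36, E42, PDVIT	missense_variant	MAP kinase kinase kinase 66
Solyc09g005080	E36, PDVIT	missense_variant	Verticillium resistance
Solyc09g007110	E36 (5), E45 (5), E48 (5), PDVIT (5)	missense_variant	Leucine-rich receptor-like protein kinase family protein
Solyc09g011320	E11, E109	missense_variant	Serine/threonine-protein kinase
Solyc09g074240	E11, E36, E109, PDVIT	missense_variant	Protein kinase domain
Solyc09g091580	E11, E55	missense_variant	Protein kinase domain
Solyc09g091990	E42, E48, PDVIT	missense_variant	Receptor like protein kinase S.2
Solyc10g005140	E55	missense_variant	probably inactive receptor-like protein kinase At2g46850
Solyc10g084390	E55	missense_variant	Protein kinase superfamily protein
Solyc11g007280	E42	missense_variant	Pleiotropic drug resistance protein 2
Solyc11g011080	E11 (3), E36 (3), E109 (3)	missense_variant	Disease resistance protein (TIR-NBS-LRR class)
Solyc11g011090	E11 (2), E36, E109 (2)	missense_variant	Disease resistance protein (TIR-NBS-LRR class)
Solyc11g011180	E11, E36, E109	missense_variant	Lrr receptor-like serinethreonine-protein kinase gso1
Solyc11g013880	E11	missense_variant	G-type lectin S-receptor-like serine/threonine-protein kinase
Solyc11g018690	E11, E42, PDVIT	missense_variant	ABC transporter G family member 25
Solyc11g020230	E11, PDVIT	missense_variant	Serine/threonine-protein kinase-like protein CCR4
Solyc11g020280	E11, PDVIT	missense_variant	Receptor-like protein kinase
Solyc11g033270	E11, PDVIT	missense_variant	MAP kinase kinase kinase 82
Solyc11g042990	E11, PDVIT	missense_variant	Kinase protein
Solyc11g056680	E11, PDVIT	missense_variant	Leucine-rich repeat receptor-like protein
Solyc12g016220	E55	missense_variant	Disease resistance protein
Solyc12g021280	E11, E36, E45, E48, E55	missense_variant	Serine/threonine-protein kinase STN7, chloroplastic
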