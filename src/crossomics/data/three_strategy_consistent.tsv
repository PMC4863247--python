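# curated published fold-change/p-value table, T24M vs T24, three fractionation strategies
accession	protein_name	fc_CE	p_CE	fc_ERGolgi	p_ERGolgi	fc_CM	p_CM	mrna_supported
P08582	Melanotransferrin	only_T24M	0.01	2.52	0.01	only_T24M	0.01	1
P05161	Ubiquitin-like protein ISG15	4.99	0.01	6.06	0.01	only_T24M	0.01	1
Q13642	Four and a half LIM domains protein 1	2.31	0.01	1.86	0.01	10.8	0.01	1
P61769	Beta-2-microglobulin	1.78	0.05	16.68	0.03	1.60	0.03	1
Q14011	Cold-inducible RNA-binding protein	1.52	0.01	only_T24M	0.02	1.76	0.05	1
Q09666	Neuroblast differentiation-associated protein AHNAK	0.64	0.01	0.52	0.01	0.54	0.01	1
Q01813	6-phosphofructokinase type C	0.54	0.01	0.30	0.01	only_T24	0.02	1
P15559	NAD(P)H dehydrogenase [quinone] 1	0.54	0.01	0.51	0.05	0.12	0.01	1
P06396	Gelsolin	0.53	0.01	0.51	0.01	0.48	0.01	1
Q9UBG0	C-type mannose receptor 2	0.52	0.03	0.4	0.02	0.54	0.01	1
P11413	Glucose-6-phosphate 1-dehydrogenase	0.52	0.01	0.51	0.01	0.56	0.01	1
P08670	Vimentin	only_T24M	0.01	only_T24M	0.01	only_T24M	0.01	0
P28838	Cytosol aminopeptidase	2.22	0.01	3.57	0.01	2.46	0.01	0
P13797	Plastin-3	1.79	0.01	1.63	0.01	1.66	0.01	0
P05362	Intercellular adhesion molecule 1	1.64	0.01	2.3	0.01	3.05	0.01	0
O95336	6-phosphogluconolactonase	1.60	0.01	3.79	0.01	4.15	0.01	0
P26639	Threonine--tRNA ligase cytoplasmic	1.54	0.01	1.50	0.01	2.32	0.01	0
P00492	Hypoxanthine-guanine phosphoribosyltransferase	1.51	0.01	2.12	0.01	1.77	0.01	0
Q8IV08	Phospholipase D3	1.86	0.01	only_T24M	0.02	only_T24M	0.02	0
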