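protein_id	description	log2_ratio	p_value
Os02g06410.1	Putative SNF-1 related protein kinase	-8.13	0.01
Os12g29400.1	GRAM domain containing protein, expressed	-8.02	0.02
Os05g39250.1	PEBP (phosphatidylethanolamine-binding) family protein	-7.67	0.02
Os05g49440.2	DUF1264 domain containing protein	-7.62	0.02
Os03g15960.1	17.9 kDa heat shock protein	-7.49	0.02
Os03g14180.1	26.7 kDa heat shock protein	-7.47	0.03
Os02g32860.1	Poly [ADP-ribose] polymerase 3	-7.46	0.03
Os03g19290.1	Chloroplastic outer enveloppe pore protein	-7.42	0.03
Os03g04410.1	Aconitase	-7.41	0.03
Os05g37330.1	60S acidic ribosomal protein	-7.38	0.03
Os02g51750.1	Annexin	-7.32	0.03
Os10g30150.1	Universal stress protein	-7.22	0.03
Os03g06360.1	Late embryogenesis abundant protein D-34	-7.18	0.03
Os01g50910.1	Late embryogenesis abundant protein LEA_4 domain	-6.87	0.04
Os05g44340.1	Chaperone protein ClpB1, heat shock protein 101	-6.86	0.04
Os08g41390.1	Putative 70 kDa peptidylprolyl isomerase	-6.74	0.04
Os10g17280.1	ATP synthase gamma chain	-6.71	0.04
Os07g42490.1	Sucrose synthase 3	8.80	0.00
Os07g11630.1	LTPL163 LTP family protein	7.94	0.00
Os12g14070.1	70 kDa heat shock-related protein	7.93	0.00
Os05g26350.1	13 kDa prolamin PROLM4	6.93	0.00
Os05g41970.1	19 kDa globulin	6.74	0.00
Os11g47520.1	Xylanase inhibitor protein 2	6.74	0.00
Os06g09450.1	Sucrose synthase 4	6.62	0.00
Os02g14600.1	Glutelin GluB-7	6.53	0.00
Os02g32660.1	Starch branching enzyme	6.53	0.00
Os07g11410.1	Seed allergenic protein RAG2	6.19	0.00
Os01g44220.1	ADP-glucose pyrophosphorylase	6.08	0.00
Os06g51084.1	Starch branching enzyme 1	6.07	0.00
Os07g10570.1	13 kDa prolamin PROLM25	5.98	0.00
Os02g15090.1	Glutelin GluD-1	5.84	0.00
Os06g04200.1	Granule-bound starch synthase 1 (Waxy)	5.81	0.00
Os05g33570.1	PPDK1 Pyruvate phosphate dikinase 1	5.79	0.00
Os07g11650.1	LTPL164 LTP family protein	5.46	0.01
Os07g11380.1	Seed allergenic protein RAG2	5.33	0.01
Os07g10580.1	13 kDa prolamin PROLM26	5.29	0.01
Os07g11360.1	Seed allergenic protein	5.27	0.01
Os06g22060.1	6-phosphofructokinase pyrophosphate dependent	5.11	0.01
Os02g25640.1	Glutelin GluC-1	5.03	0.01
Os02g15169.1	Glutelin GluB-1b	4.88	0.01
Os07g11510.1	Seed allergenic protein	4.82	0.01
Os07g34520.1	Isocitrate lyase	4.79	0.01
Os02g16820.1	Glutelin GluB-5	4.77	0.01
Os07g11330.1	Seed allergenic protein	4.68	0.01
Os04g40660.1	MA3 domain containing protein	4.59	0.01
Os06g31070.1	13 kDa prolamin PROLM24	4.57	0.01
Os03g55090.1	Starch phosphorylase	4.54	0.01
Os03g16440.1	Translocon at outer-enveloppe membrane of chloroplast	4.51	0.01
Os03g31360.1	Glutelin GluA-3	4.34	0.02
Os04g33150.1	desiccation-related protein	4.14	0.02
Os10g35010.1	Translocon at inner-enveloppe membrane of chloroplast	4.00	0.02
Os02g15150.1	Glutelin GluB-2	3.79	0.03
Os10g26060.1	Glutelin GluA-2	3.69	0.03
Os06g48750.1	eIF4A-1 Eukaryotic translation initiation factor 4A-1	3.56	0.03
Os02g50350.1	Dihydropyrimidine dehydrogenase	3.55	0.03
Os01g55690.1	Glutelin GluA-1	3.51	0.03
Os11g40530.1	LTPL162 LTP family protein	3.44	0.03
Os07g11900.1	13 kDa prolamin PROLM19	3.30	0.04
Os01g47410.1	Aspartic proteinase oryzasin-1	3.24	0.04
Os06g46284.1	Probable alpha-glucosidase	3.15	0.04
Os06g30370.1	OsMFT1 homologous to Mother of FT and TFL1	3.08	0.05
Os07g11310.1	LTPL166 LTP family protein	3.06	0.05
Os05g02060.1	Chloroplastic outer envelope pore protein	3.03	0.05
Os02g32030.1	Elongation factor	3.00	0.05
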