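protein_id	family	description	specificity	rank	log2_ratio
Os08g36150.1	ASA1	Heat shock protein 90 co-chaperone	Common	NA	-3.9
Os05g44340.1	clpA/clpB	Chaperone protein ClpB1	Common	NA	-6.9
Os10g42439.1	DnaJ	DnaJ homolog	Embryo	1312	NA
Os01g04370.1	HSP20	16.9 kDa class I heat shock protein 1	Common	NA	-5.4
Os01g08860.1	HSP20	18.0 kDa class II heat shock protein	Embryo	74	NA
Os02g52150.1	HSP20	24.1 kDa heat shock protein	Embryo	362	NA
Os02g54140.1	HSP20	18.6 kDa class III heat shock protein	Embryo	49	NA
Os03g14180.1	HSP20	Chloroplastic 26.7 kDa heat shock protein	Common	NA	-7.5
Os03g15960.1	HSP20	17.9 kDa class I heat shock protein	Common	NA	-7.5
Os03g16020.1	HSP20	17.4 kDa class I heat shock protein	Endosperm	75	NA
Os03g16030.1	HSP20	18.1 kDa class I heat shock protein	Embryo	394	NA
Os03g16040.1	HSP20	17.7 kDa class I heat shock protein	Embryo	195	NA
Os04g36750.1	HSP20	23.2 kDa heat shock protein	Embryo	93	NA
Os06g11610.1	HSP20	Mitochondrial 26.2 kDa heat shock protein	Embryo	1210	NA
Os11g13980.1	HSP20	21.9 kDa heat shock protein	Embryo	1350	NA
Os01g08560.1	HSP70	70 kDa Heat shock protein	Common	NA	-4.5
Os01g62290.1	HSP70	70 kDa Heat shock protein	Common	NA	-3.6
Os02g48110.1	HSP70	70 kDa Heat shock protein	Common	NA	-2.5
Os02g53420.1	HSP70	70 kDa Heat shock protein	Common	NA	-2.1
Os03g02260.1	HSP70	70 kDa Heat shock protein	Embryo	135	NA
Os03g11910.1	HSP70	70 kDa Heat shock protein	Embryo	218	NA
Os03g16860.1	HSP70	70 kDa Heat shock protein	Embryo	280	NA
Os03g16920.1	HSP70	70 kDa Heat shock protein	Common	NA	-3.5
Os03g60620.1	HSP70	70 kDa Heat shock protein	Common	NA	0.6
Os05g08840.1	HSP70	70 kDa Heat shock protein	Common	NA	-4.0
Os05g23740.1	HSP70	70 kDa Heat shock protein	Common	NA	0.8
Os05g38530.1	HSP70	70 kDa Heat shock protein	Embryo	206	NA
Os11g47760.1	HSP70	70 kDa Heat shock protein	Common	NA	-2.3
Os12g14070.1	HSP70	70 kDa Heat shock protein	Common	NA	7.9
Os04g01740.1	HSP90	90kDa heat shock protein	Embryo	92	NA
Os06g50300.1	HSP90	Endoplasmin homolog	Common	NA	-2.9
Os08g38086.3	HSP90	90 kDa heat shock protein	Endosperm	109	NA
Os08g39140.1	HSP90	Heat shock protein 81-1	Embryo	129	NA
Os09g29840.1	HSP90	90 kDa heat shock protein	Common	NA	0.5
Os09g30412.1	HSP90	Heat shock protein 81-2	Embryo	551	NA
Os09g30418.1	HSP90	Heat shock protein 81-3	Common	NA	0.3
Os12g32986.1	HSP90	90 kDa heat shock protein	Embryo	179	NA
Os01g06630.1	LEA	Late embryogenesis abundant LEA_5	Embryo	21	NA
Os01g12580.1	LEA	Late embryogenesis abundant LEA_2	Common	NA	-5.5
Os01g50700.1	LEA	Dehydrin Rab25	Common	NA	-4.4
Os01g50910.1	LEA	Late embryogenesis abundant LEA_4	Common	NA	-6.9
Os02g15250.1	LEA	Late embryogenesis abundant protein	Common	NA	-4.5
Os02g44870.1	LEA	Dehydrin	Embryo	723	NA
Os03g06360.1	LEA	Late embryogenesis abundant protein	Common	NA	-7.2
Os03g20680.1	LEA	Late embryogenesis abundant protein 1	Common	NA	-4.7
Os03g53620.1	LEA	Late embryogenesis abundant protein	Embryo	262	NA
Os03g62620.2	LEA	Late embryogenesis abundant LEA_2	Common	NA	-3.3
Os04g52110.1	LEA	Late embryogenesis abundant protein	Common	NA	-5.0
Os05g28210.1	LEA	Embryonic abundant protein 1	Embryo	14	NA
Os05g46480.1	LEA	Late embryogenesis abundant protein	Common	NA	-5.9
Os05g50710.1	LEA	Late embryogenesis abundant LEA_2	Embryo	321	NA
Os06g23350.1	LEA	Late embryogenesis abundant protein	Common	NA	-4.5
Os08g23870.1	LEA	Late embryogenesis abundant LEA_1	Embryo	110	NA
Os11g26570.1	LEA	Dehydrin	Common	NA	-2.98
Os11g26750.1	LEA	Dehydrin Rab16D	Embryo	1396	NA
Os11g26780.1	LEA	Dehydrin Rab16B GN = RAB16B	Embryo	330	NA
Os12g43140.1	LEA	Late embryogenesis abundant protein	Embryo	69	NA
Os02g43020.1	TPR	Heat shock protein stress-induced TPLR_2	Common	NA	-2.4
Os08g34150.1	Lipocalin	OsTIL-2 Temperature-induced lipocalin 2	Embryo	644	NA
Os02g39930.1	Lipocalin	OsTIL-1 Temperature-induced lipocalin 1	Embryo	1424	NA
Os03g31300.1	clpA/clpB	Chloroplastic chaperone protein ClpB2	Common	NA	-0.12
Os02g08490.1	clpA/clpB	Mitochondrial chaperone protein ClpB3	Embryo	165	NA
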