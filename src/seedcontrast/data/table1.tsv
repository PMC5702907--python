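compound	class	log2_ratio	fdr	specific_tissue
γ-tocopherol	Apolar	NA	NA	Embryo
Maltotriose	Carbohydrate	NA	NA	Embryo
Ascorbate	Organic acids	NA	NA	Endosperm
Feruoylquinic acid	Organic acids	NA	NA	Embryo
Adenosine-5-P	Purine_Pyrimidine	NA	NA	Embryo
Galactinol_isomer_1	Sugar alcohol	NA	NA	Embryo
Galactinol_isomer_2	Sugar alcohol	NA	NA	Embryo
4-hydroxyproline	Amino acids	1.95	0.05	NA
Alanine	Amino acids	0.88	0.04	NA
beta-Alanine	Amino acids	1.76	0.03	NA
3-cyano-alanine	Amino acids	3.31	0.03	NA
Cystein	Amino acids	1.77	0.05	NA
4-Aminobutyrate (GABA)	Amino acids	2.29	0.01	NA
Glutamine	Amino acids	3.00	0.01	NA
Isoleucine	Amino acids	2.30	0.04	NA
Leucine	Amino acids	2.21	0.03	NA
Lysine	Amino acids	1.32	0.00	NA
Ornithine	Amino acids	0.84	0.03	NA
Phenylalanine	Amino acids	2.57	0.03	NA
Pyroglutamate	Amino acids	0.97	0.03	NA
Serine	Amino acids	2.05	0.03	NA
Threonine	Amino acids	1.59	0.04	NA
Tryptophan	Amino acids	1.20	0.01	NA
Valine	Amino acids	2.39	0.04	NA
α-Tocopherol	Apolar	-2.55	0.03	NA
β-Sitosterol	Apolar	2.57	0.00	NA
Campesterol	Apolar	1.72	0.00	NA
Monopalmitin	Apolar	3.83	0.03	NA
Monostearin	Apolar	4.62	0.02	NA
Stigmasterol	Apolar	3.18	0.00	NA
N-acetylmannosamine	Other	2.49	0.02	NA
Arabinose	Carbohydrate	4.38	0.02	NA
Cellobiose	Carbohydrate	1.95	0.03	NA
Galactose	Carbohydrate	5.64	0.02	NA
Glucopyranose	Carbohydrate	4.30	0.02	NA
Mannose	Carbohydrate	1.54	0.01	NA
Melibiose	Carbohydrate	1.49	0.01	NA
Ribose	Carbohydrate	5.07	0.01	NA
Sedoheptulose	Carbohydrate	3.56	0.02	NA
Trehalose	Carbohydrate	1.53	0.00	NA
Xylose	Carbohydrate	4.42	0.02	NA
Raffinose	Carbohydrate	-0.76	0.02	NA
Sucrose	Carbohydrate	0.98	0.01	NA
Linoleic acid	Fatty acids	4.76	0.01	NA
Linolenic acid	Fatty acids	4.61	0.02	NA
Caffeate	Organic acids	4.73	0.03	NA
Citrate	Organic acids	-1.24	0.01	NA
Erythronate	Organic acids	3.57	0.05	NA
Fumarate	Organic acids	3.20	0.05	NA
4-hydroxybutanoate	Organic acids	5.34	0.01	NA
Glucaric acid	Organic acids	-2.69	0.01	NA
Gluconate	Organic acids	1.96	0.03	NA
Glycerate	Organic acids	3.80	0.03	NA
Glycolate	Organic acids	4.57	0.03	NA
Malate	Organic acids	2.77	0.01	NA
Maleate	Organic acids	3.90	0.01	NA
Malonate	Organic acids	2.35	0.05	NA
Nicotinate	Organic acids	2.11	0.03	NA
Phosphate	Organic acids	1.15	0.01	NA
Pipecolate	Organic acids	0.68	0.01	NA
Salicylate	Organic acids	4.03	0.05	NA
Sinapinate	Organic acids	3.90	0.03	NA
Sinapinate-trans	Organic acids	4.01	0.01	NA
Succinate	Organic acids	3.28	0.03	NA
Threonate	Organic acids	1.50	0.00	NA
Spermidine	Polyamine	2.76	0.01	NA
Guanine	Purine_Pyrimidine	4.31	0.03	NA
Uracil	Purine_Pyrimidine	3.62	0.04	NA
Erythritol	Sugar alcohol	3.59	0.00	NA
Glycerol	Sugar alcohol	4.19	0.03	NA
Glycerol-2-P	Sugar alcohol	1.56	0.01	NA
Glycerol-3-P	Sugar alcohol	0.56	0.01	NA
Inositol_isomer_3	Sugar alcohol	2.15	0.03	NA
Inositol_isomer_4	Sugar alcohol	1.59	0.01	NA
Inositol_isomer_5	Sugar alcohol	2.66	0.03	NA
Inositol-1-P	Sugar alcohol	3.15	0.03	NA
Mannitol	Sugar alcohol	3.98	0.03	NA
Digalactosylglycerol	Sugar alcohol	-0.61	0.00	NA
Galactosylglycerol	Sugar alcohol	4.38	0.03	NA
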