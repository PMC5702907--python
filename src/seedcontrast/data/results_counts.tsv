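key	value
proteome_embryo_detected	2099
proteome_endosperm_detected	786
proteome_common	673
proteome_endosperm_favored	76
proteome_embryo_favored	267
proteome_zscore_significant	64
proteome_zscore_endosperm_more_abundant	47
transcriptome_embryo_detected	16998
transcriptome_endosperm_detected	15339
transcriptome_embryo_specific	2771
transcriptome_endosperm_specific	1112
transcriptome_common	14227
metabolome_common	117
metabolome_differential	72
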