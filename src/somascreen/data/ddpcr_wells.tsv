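assay	sample_label	alt	ref
EVI5_T54A	CD3_T_cells	12.6	1000
EVI5_T54A	CD8_TEMRA_cells	11.3	331
EVI5_T54A	Remaining_CD8_T_cells	0	247
EVI5_T54A	CD4_TEM_cells	0	172
EVI5_T54A	Remaining_CD4_T_cells	0	197
EVI5_T54A	CD19_B_cells	0.34	688.5
EVI5_T54A	Other_immune_cells	0.22	546
EVI5_T54A	Negative_control	0.16	974.5
LTBP1_D1156V	CD8_TEMRA_cells	0	233
LTBP1_D1156V	Remaining_CD8_T_cells	0	184
LTBP1_D1156V	CD4_TEM_cells	8.5	129
LTBP1_D1156V	Remaining_CD4_T_cells	0	89
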