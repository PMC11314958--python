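roi_name,atlas_label
superior_frontal,R_SFG
anterior_cingulate,R_ACG
posterior_cingulate,R_PCG
dorsal_anterior_insula,R_dAIns
middle_temporal,R_MTG
entorhinal,R_ENT
parahippocampal,R_PhG
fusiform,R_FuG
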