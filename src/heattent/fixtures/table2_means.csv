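trait,p_T,p_G,p_TxG,control_mean,hnt_mean,control_letter,hnt_letter
grain_filling_duration_d,0.004,<0.001,0.031,42.0,38.9,a,b
kernel_weight_200_g,<0.001,<0.001,0.012,5.7,5.3,a,b
grain_yield_g_m2,0.002,<0.001,0.729,512.8,424.9,a,b
seed_number_m2,0.012,<0.001,0.874,18112.6,15879.8,a,b
biomass_g_m2,0.11,<0.001,0.649,607.7,570.0,a,a
harvest_index,0.013,<0.001,0.122,0.38,0.35,a,b
starch_pct,<0.001,<0.001,0.6149,59.0,50.0,a,b
protein_pct,0.431,<0.001,0.932,14.1,14.5,a,a
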