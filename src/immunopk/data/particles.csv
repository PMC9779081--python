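nanoparticle,lot_number,mean_hydrodynamic_diameter_nm,pdi,zeta_potential_mv,zeta_potential_sd_mv,protein_concentration_ug_per_mg
BNF-Plain,0901810,102.3,0.115,-3.4,7.0,
BNF-HER,1261810,140.9,0.117,-6.6,3.6,32.6
BNF-IgG,0981810,130.0,0.109,-5.1,6.6,35.5
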