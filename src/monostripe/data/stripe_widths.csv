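sample_id,figure_panel,lipid_system,dppc_chirality,ratio_b,dchol_mol_pct,width_um,width_sd_um,delta_nm,pressure_mN_m,temperature_C
hd_r_3_equil,Fig1F,DPPC:HD,r,3,1.5,6.0,0.3,1,7,22
hd_r_5_equil,Fig1L,DPPC:HD,r,5,1.5,4.1,0.2,1,7,22
hd_r_9_equil,Fig1R,DPPC:HD,r,9,1.5,4.0,0.2,1,7,22
hd_rac_3_equil,Fig2D,DPPC:HD,rac,3,1.5,6.5,0.4,1,7,22
hd_rac_5_equil,Fig2J,DPPC:HD,rac,5,1.5,4.4,0.2,1,7,22
hd_rac_9_equil,Fig2O,DPPC:HD,rac,9,1.5,4.0,0.2,1,7,22
hd_rac_3_compressed,Fig2E,DPPC:HD,rac,3,1.5,6.8,0.4,1,,22
hd_rac_5_compressed,Fig2K,DPPC:HD,rac,5,1.5,2.9,0.1,1,,22
hd_rac_9_compressed,Fig2Q,DPPC:HD,rac,9,1.5,2.0,0.1,1,,22
pa_r_3_equil,Fig3D,DPPC:PA,r,3,1.5,6.5,0.4,1,7,22
pa_r_5_equil,Fig3H,DPPC:PA,r,5,1.5,4.0,0.2,1,7,22
pa_r_9_equil,Fig3L,DPPC:PA,r,9,1.5,4.2,0.2,1,7,22
hd_r_3_plateau,Fig10A,DPPC:HD,r,3,1.5,7.0,1.0,1,,22
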