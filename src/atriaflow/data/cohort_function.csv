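subject,group,laa_thrombus_or_tia,atrial_fibrillation,sinus_rhythm,eqv_left_pct,eqv_right_pct,mean_la_vol_ml,v_la_min_ml,v_la_max_ml,mean_laa_vol_ml,v_laa_min_ml,v_laa_max_ml,lvsv_ml,ostium_area,ostium_ar,v_la_pre_a_ml,sphericity,global_ef,laa_ef,lv_ef,expansion_index,passive_ef,booster_ef,conduit_fraction,pvs_ml,pvd_ml,pvs_pvd_ratio,pva_ml,pva_duration_cycles,a_wave_duration_cycles,pva_a_wave_ratio,e_a_ratio,re_mv
1,normal,no,no,yes,42,58,86.6,59.6,108,6.94,4.32,8.97,72.2,4.17,1.53,94.3,0.80,0.45,0.52,0.67,0.81,0.13,0.37,0.33,43,65,0.66,17,0.11,0.22,0.49,1.64,4297
2,normal,no,no,yes,46,54,70.1,49.0,91.2,4.85,3.14,6.28,84.4,4.01,1.39,72.3,0.82,0.46,0.50,0.67,0.86,0.21,0.32,0.50,38,58,0.66,7.3,0.11,0.25,0.43,2.36,6266
3,normal,no,no,yes,42,58,115,87.2,145,14.3,10.2,17.9,98,7.65,1.49,119,0.78,0.40,0.43,0.78,0.66,0.18,0.27,0.41,51,60,0.84,12,0.13,0.30,0.44,3.03,6315
4,normal,no,no,yes,40,60,84.2,60.3,108,3.13,1.45,4.23,106,2.26,1.10,87.3,0.77,0.44,0.66,0.68,0.80,0.19,0.31,0.55,48,65,0.72,2.7,0.08,0.24,0.33,2.24,8402
5,normal,no,no,yes,34,64,96.1,68.6,121,3.64,2.24,4.65,102,3.00,1.19,98.5,0.83,0.43,0.52,0.65,0.76,0.18,0.30,0.49,53,54,0.99,2.73,0.19,0.28,0.68,2.23,6244
6,impaired,tias,persistent,no,51,49,145,119,155,10.7,9.10,11.6,66.7,7.22,1.45,149,0.86,0.23,0.22,0.66,0.30,0.04,0.20,0.46,36,52,0.69,13,0.12,0.18,0.64,2.05,4361
7,impaired,yes,persistent,no,39,61,157,150,165,15.5,13.8,17.4,75,7.29,1.45,153,0.83,0.09,0.21,0.61,0.10,0.07,0.02,0.80,17,63,0.27,0.14,0.039,0.21,0.18,3.86,4111
8,impaired,yes,persistent,no,46,54,180,157,205,22.0,19.8,24.7,130,8.42,1.83,178,0.81,0.23,0.20,0.42,0.31,0.13,0.12,0.63,49,94,0.52,1.4,0.068,0.23,0.30,3.65,8058
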