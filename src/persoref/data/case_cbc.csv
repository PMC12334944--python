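measurand,units,hsp_mean,hsp_sd,hsp_mean_decimals,hsp_sd_decimals,n,cv_i,cv_a,cv_t,ii,cv_g_derived,pop_ri_lower,pop_ri_upper,display_decimals,exp_prri_pop_lower,exp_prri_pop_upper,exp_prri_pop_decimals,exp_rcv_pop,exp_prri_ind_lower,exp_prri_ind_upper,exp_prri_ind_decimals,exp_rcv_ind
leukocytes,x10^9/L,4.8,0.5,1,1,3,11.10,1.26,9.45,0.65,17.08,3.5,9.5,1,3.7,6.0,1,30.96,2.5,7.0,1,26.20
neutrophils,x10^9/L,3.0,0.3,1,1,3,14.10,1.46,9.83,0.58,24.31,1.8,6.3,1,2.0,3.9,1,39.29,1.5,4.4,1,27.25
lymphocytes,x10^9/L,1.4,0.1,1,1,3,10.80,3.55,6.62,0.48,22.50,1.1,3.2,1,1.0,1.7,1,31.51,0.9,1.8,1,18.34
monocytes,x10^9/L,0.3,0.1,1,1,3,13.30,7.08,24.24,0.60,22.17,0.1,0.6,1,0.2,0.4,1,41.77,-0.1,0.7,1,67.20
eosinophils,x10^9/L,0.1,0.0,1,1,3,15.00,16.70,37.50,0.24,62.50,0.02,0.52,2,0.04,0.12,2,62.23,-0.1,0.2,1,103.94
basophils,x10^9/L,0.04,0.0,2,1,3,12.40,14.35,0.00,0.44,28.18,0.0,0.06,2,0.02,0.06,2,52.56,0.0,0.04,2,0.00
erythrocytes,x10^12/L,4.45,0.17,2,2,3,2.80,0.67,3.82,0.40,7.000,3.8,5.1,2,4.16,4.74,2,7.98,3.61,5.30,2,10.59
hematocrit,L/L,0.420,0.020,3,3,3,2.80,0.54,4.76,0.50,5.600,0.35,0.45,3,0.390,0.450,3,7.90,0.320,0.520,3,13.20
hemoglobin,g/L,141,5,0,0,3,2.70,0.25,3.36,0.44,6.136,115,150,0,132,149,0,7.52,117,164,0,9.32
platelets,x10^9/L,217,25,0,0,3,6.40,0.17,11.43,0.47,13.62,125,350,0,185,249,0,18.06,94,341,0,31.69
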