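# Cohort of 6 healthy volunteers (HG) and 12 repaired-TOF patients split by
# post-PVR ejection-fraction change into better (BG) and worse (WG) outcome
# groups, with per-participant mean RV max-principal stress (kPa) and strain
# (dimensionless) at begin-filling (bf), end-filling (ef), begin-ejection (be)
# and end-ejection (ee) from one-reference (1g) and two-reference (2g) models.
# Healthy indexed volumes were not reported and are left blank.  The garbled
# WG mean delta-EF summary cell in the source table is not stored; group
# summaries are always recomputed from the per-participant rows below.
id,group,sex,age_y,p_max_mmHg,edv_cm3,edvi_ml_m2,esv_cm3,esvi_ml_m2,ef_pct,delta_ef_pct,stress_1g_bf,stress_1g_be,stress_2g_bf,stress_2g_ef,stress_2g_be,stress_2g_ee,strain_1g_bf,strain_1g_be,strain_2g_bf,strain_2g_ef,strain_2g_be,strain_2g_ee
P1,HG,F,46.7,22,128.4,,46.9,,63,,1.91,48.18,1.91,22.38,49.57,8.07,0.031,0.637,0.031,0.648,0.728,0.100
P2,HG,M,23.6,27.9,226.6,,105.4,,53,,1.90,42.13,1.90,17.40,45.13,7.89,0.026,0.531,0.026,0.531,0.636,0.082
P3,HG,M,20.8,24,231.7,,107.0,,54,,1.68,33.37,1.68,14.79,37.55,7.60,0.032,0.523,0.032,0.530,0.612,0.108
P4,HG,M,19.4,23.8,213.5,,94.2,,56,,2.35,39.52,2.35,17.15,39.89,8.48,0.016,0.486,0.016,0.483,0.582,0.089
P5,HG,M,17.7,24.3,233.7,,105.5,,55,,2.76,40.42,2.76,17.33,45.19,9.13,0.042,0.544,0.042,0.544,0.611,0.084
P6,HG,M,6.7,24.8,67.6,,28.2,,58,,2.14,47.15,2.14,19.99,50.21,10.06,0.038,0.575,0.038,0.564,0.669,0.120
P7,BG,M,47.7,31,408.8,192.68,254.8,120.10,37.7,-2.6,2.84,41.77,2.84,19.17,43.29,13.87,0.021,0.339,0.021,0.338,0.442,0.093
P8,BG,M,50.0,33,364.6,205.10,239.5,134.75,34.3,-2.9,4.15,54.51,4.15,25.36,55.70,17.68,0.023,0.278,0.023,0.280,0.376,0.092
P9,BG,F,42.0,45,323.3,178.60,177.8,98.24,45.0,4.0,4.90,87.25,4.90,35.16,91.36,18.18,0.032,0.462,0.032,0.476,0.591,0.111
P10,BG,F,14.3,29,204.0,175.86,104.3,89.91,48.8,5.6,2.94,57.38,2.94,22.80,62.87,13.13,0.042,0.491,0.042,0.489,0.601,0.122
P11,BG,F,15.3,15,193.7,186.25,105.1,101.06,45.7,6.6,1.51,27.68,1.51,11.15,26.02,5.98,0.027,0.414,0.027,0.421,0.528,0.093
P12,BG,M,17.0,27,188.3,229.63,108.3,132.07,42.5,2.0,2.10,36.08,2.10,14.90,38.34,7.74,0.033,0.368,0.033,0.370,0.472,0.093
P13,WG,F,56.9,41,385.1,224.73,184.6,106.80,52.1,-18.0,5.78,116.33,5.78,48.87,122.54,22.04,0.051,0.609,0.051,0.600,0.724,0.124
P14,WG,M,11.6,36,204.2,167.35,121.3,99.39,40.6,-8.4,3.85,49.81,3.85,21.11,52.00,14.42,0.028,0.335,0.028,0.328,0.424,0.078
P15,WG,M,43.5,65,665.1,263.99,464.0,184.20,30.2,-15.2,5.77,76.22,5.77,29.93,80.48,30.30,0.018,0.217,0.018,0.220,0.322,0.084
P16,WG,M,54.1,63,334.8,155.38,170.8,79.25,49.0,-7.0,4.14,98.91,4.14,37.01,108.67,17.12,0.037,0.567,0.037,0.562,0.698,0.120
P17,WG,F,44.6,50,299.0,184.57,186.0,114.81,37.8,-12.3,6.81,92.57,6.81,39.84,91.76,29.37,0.028,0.331,0.028,0.333,0.428,0.107
P18,WG,F,45.3,49,571.1,291.38,371.3,189.44,35.0,-13.4,4.67,65.52,4.67,29.25,66.21,20.63,0.022,0.310,0.022,0.278,0.411,0.087
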