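# Aluminium (Z=13) mass attenuation coefficient, total with coherent.
# Columns: energy_keV  mu_over_rho_cm2_per_g
20 3.441
30 1.128
40 0.5685
50 0.3681
60 0.2778
80 0.2018
100 0.1704
150 0.1378
200 0.1223
300 0.1042
400 0.09276
500 0.08445
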