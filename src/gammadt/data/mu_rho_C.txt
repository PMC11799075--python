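# Carbon (Z=6) mass attenuation coefficient, total with coherent.
# Columns: energy_keV  mu_over_rho_cm2_per_g
20 0.4420
30 0.2562
40 0.2076
50 0.1871
60 0.1753
80 0.1610
100 0.1514
150 0.1347
200 0.1229
300 0.1066
400 0.09546
500 0.08715
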