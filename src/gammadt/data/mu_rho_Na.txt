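# Sodium (Z=11) mass attenuation coefficient, total with coherent (approximate).
# Columns: energy_keV  mu_over_rho_cm2_per_g
20 1.980
30 0.7090
40 0.4050
50 0.3030
60 0.2630
80 0.2050
100 0.1780
150 0.1520
200 0.1380
300 0.1190
400 0.1065
500 0.0970
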