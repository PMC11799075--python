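# Hydrogen (Z=1) mass attenuation coefficient, total with coherent.
# Columns: energy_keV  mu_over_rho_cm2_per_g
20 0.3695
30 0.3570
40 0.3458
50 0.3355
60 0.3260
80 0.3091
100 0.2944
150 0.2651
200 0.2429
300 0.2112
400 0.1893
500 0.1729
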