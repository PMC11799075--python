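# Lead (Z=82) mass attenuation coefficient, total with coherent.
# K edge at 88.005 keV represented by a double grid point.
# Columns: energy_keV  mu_over_rho_cm2_per_g
20 86.36
30 30.32
40 14.36
50 8.041
60 5.021
80 2.419
88.004 1.910
88.006 7.683
100 5.549
150 2.014
200 0.9985
300 0.4031
400 0.2323
500 0.1614
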