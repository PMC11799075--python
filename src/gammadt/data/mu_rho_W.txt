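# Tungsten (Z=74) mass attenuation coefficient, total with coherent.
# K edge at 69.525 keV represented by a double grid point.
# Columns: energy_keV  mu_over_rho_cm2_per_g
20 65.73
30 22.73
40 10.67
50 5.949
60 3.713
69.524 2.552
69.526 11.23
80 7.810
100 4.438
150 1.581
200 0.7844
300 0.3238
400 0.1925
500 0.1378
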