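# Iodine (Z=53) mass attenuation coefficient, total with coherent (approximate).
# K edge at 33.17 keV represented by a double grid point.
# Columns: energy_keV  mu_over_rho_cm2_per_g
20 25.43
30 8.561
33.169 6.553
33.171 36.00
40 22.10
50 12.32
60 7.579
80 3.510
100 1.942
150 0.6978
200 0.3871
300 0.2099
400 0.1456
500 0.1153
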