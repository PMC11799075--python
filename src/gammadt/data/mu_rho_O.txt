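# Oxygen (Z=8) mass attenuation coefficient, total with coherent.
# Columns: energy_keV  mu_over_rho_cm2_per_g
20 0.8651
30 0.3779
40 0.2585
50 0.2132
60 0.1907
80 0.1678
100 0.1551
150 0.1361
200 0.1237
300 0.1070
400 0.09566
500 0.08729
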