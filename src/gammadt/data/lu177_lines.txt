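# Main photon emissions of Lu-177 (gammas and X-rays).
# Columns: energy_keV  intensity_fraction_per_decay
208.4 0.110
113.0 0.064
64.9 0.002
63.2 0.009
55.8 0.028
54.6 0.016
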