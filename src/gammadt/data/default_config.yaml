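# Default experiment configuration (documented schema, version 1).
# Every value shown here equals the packaged default; omitted keys fall back
# to the same defaults.
version: 1

phantom:
  body_half_sizes_cm: [15.0, 10.0, 15.0]   # half-extents of the water box (x, y, z)
  body_density_g_cm3: 1.0
  injected_activity_bq: 7.4e9              # typical administered Lu-177 activity
  # Organ sources; %IA values are synthetic, summing to the 52 %IA
  # whole-body retention at 24 h (liver-dominated tumor-burden scenario).
  organs:
    - {name: liver, shape: ellipsoid, center_cm: [-6.0, 3.0, 8.0], half_sizes_cm: [8.0, 6.0, 6.5], percent_ia: 40.0}
    - {name: spleen, shape: ellipsoid, center_cm: [9.0, -4.0, 6.0], half_sizes_cm: [4.0, 3.0, 4.5], percent_ia: 4.0}
    - {name: kidney_left, shape: ellipsoid, center_cm: [5.5, -5.0, 0.0], half_sizes_cm: [2.5, 2.0, 4.5], percent_ia: 4.0}
    - {name: kidney_right, shape: ellipsoid, center_cm: [-5.5, -5.0, 0.0], half_sizes_cm: [2.5, 2.0, 4.5], percent_ia: 4.0}

detectors:
  face_size_cm: [59.1, 44.5]   # Symbia-class crystal face
  standoff_cm: 1.0
  half_angle_deg: 3.0          # ideal-collimator acceptance half-angle

detector_response:
  crystal_thickness_cm: 0.95   # 9.5-mm NaI
  resolution_fwhm: 0.094       # 9.4% FWHM at the photopeak
  resolution_ref_kev: 208.4
  resolution_exponent: -0.5    # FWHM fraction scales as 1/sqrt(E)
  full_window_kev: [20.0, 400.0]
  tau_full_us: 0.5             # full-window dead time
  pileup: true

filters:
  none: null
  tfp: {material: tfp, thickness_mm: 1.2, density_g_cm3: 3.4}
  lead: {material: lead, thickness_mm: 0.5, density_g_cm3: 11.35}

windows:
  photopeak_kev: 208.4         # analysis window = photopeak +/- 10%
  sub_fraction: 0.10           # TEW sub-window width, 10% ...
  sub_width_mode: photopeak_fraction   # ... of the photopeak energy

deadtime:
  eta_default: 1.4             # window-fraction exponent when not fitted

retention:
  kind: mono                   # synthetic slow-excretion stand-in
  half_life_h: 80.0
  value: 0.52                  # 52 %IA ...
  at_h: 24.0                   # ... at 24 h after administration

run:
  n_histories: 150000
  max_scatters: 2
  target_counts: 10000         # stop once observed main-window counts exceed this
  min_seconds: 5               # floor so per-second statistics have n >= 5
  timecourse_grid_h: [24, 32, 40, 48, 56, 64, 72, 80, 88, 96, 104, 112, 120]
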