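# gammadt

Gamma-camera dead-time analysis for quantitative Lu-177 imaging.

In targeted radionuclide therapy with Lu-177 (e.g. DOTATATE for
neuroendocrine tumors), absorbed doses are estimated from gamma-camera
images acquired in the 208-keV photopeak window. At the typical 7.4-GBq
administration, counting losses from detector dead time are non-negligible
for high-tumor-burden patients — not because of the 208-keV photons
themselves (11% per decay), but because the more abundant low-energy
emissions (113-keV gamma, 55–65-keV X-rays) and body scatter flood the
detector and restart its dead period. A thin shielding filter on the
collimator face (a 0.5-mm lead sheet, or 1.2-mm tungsten "functional
paper" — cellulose sheet loaded with ~80 wt% tungsten powder) passes most
of the 208-keV photons while absorbing the low-energy flux, shortening the
*apparent* dead time without any dead-time calibration measurements.

`gammadt` implements the physics and statistics needed to study this
trade-off end to end:

- **Dead-time mathematics.** The paralyzable model
  `R_wo = R_wt · exp(−R_wt · τ_w)` (forward, and inverted on the physical
  branch via the Lambert W function), the window-fraction scaling law
  `τ_w = τ / wf^η`, and the loss metric
  `loss(%) = (R_true − R_obs)/R_true × 100`. Estimators for `τ_w` (rate-sweep
  regression and per-second closed form) and `η` are exposed as
  statsmodels-style model objects with `fit()`/`summary()`.
- **Triple-energy-window (TEW) scatter correction** producing primary
  counts from main/sub-window counts.
- **A simplified Monte Carlo phantom** (water box, organ sources with
  configurable %IA, anterior/posterior camera heads, Klein–Nishina Compton
  scatter, forced-detection estimator) producing absolute incident spectra
  with and without filters.
- **An event-level detector model**: NaI intrinsic efficiency, Gaussian
  energy blur (9.4% FWHM at 208 keV), paralyzable dead time acting on the
  full arrival stream, and optional pile-up summation — the mechanism that
  pushes the window-fraction exponent η above 1.
- **Time-course assessment**: scaling 24-h count rates along a retention
  curve to evaluate dead-time losses from 24 h to 120 h after
  administration.

## Worked example

```python
import gammadt as g

# Paralyzable-model arithmetic at a published operating point:
# 5.6 kcps true primary rate, 9.3 us apparent dead time.
obs = g.paralyzable_observed(5.6e3, 9.3e-6)
print(f"observed rate: {obs:.1f} counts/s")
print(f"dead-time loss: {g.deadtime_loss(5.6e3, obs):.2f} %")
print(f"corrected back: {g.paralyzable_true(obs, 9.3e-6):.1f} counts/s")

# Full filter comparison on the synthetic phantom (three filter
# configurations x two detectors, per-second statistics).
report = g.run_experiment(g.default_experiment_config(), seed=1)
cols = ["config", "detector", "wf_mean", "tau_w_us_mean",
        "observed_primary_rate", "loss_percent_mean"]
print(report.summary[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(report.eta.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

prints

```
observed rate: 5315.8 counts/s
dead-time loss: 5.07 %
corrected back: 5600.0 counts/s

config  detector  wf_mean  tau_w_us_mean  observed_primary_rate  loss_percent_mean
  none         1   0.2322          2.772              4.694e+04              31.97
   tfp         1   0.4029          2.148              4.573e+04              15.71
  lead         1   0.5492          1.717              3.809e+04              7.076
  none         2   0.2411          2.739              3.815e+04              23.45
   tfp         2   0.4103          2.142              3.535e+04              9.801
  lead         2   0.5487          1.761              2.909e+04              2.095

 detector  eta  eta_se
        1 1.38   0.212
        2 1.41   0.218
```

Reading the table: both filters raise the window fraction `wf`
(lead > TFP > none), which shortens the apparent dead time `τ_w`
(lead < TFP < none) and cuts the dead-time loss (none > TFP > lead), while
TFP sacrifices less of the primary count rate than lead. The fitted
window-fraction exponent η ≈ 1.4 emerges from pile-up distortion of the
recorded spectrum; with pile-up disabled the same pipeline returns η ≈ 1.
Absolute rates depend on the synthetic phantom geometry; the orderings and
the scaling law are the robust content.

A command-line interface mirrors the library:

```sh
gammadt simulate --seed 1 --out results/run1          # full comparison
gammadt deadtime --tau-us 9.3 --mode inverse --rate 5315.8
gammadt timecourse --r24 12600 --tau-us 9.3
gammadt report --per-second results/run1/per_second.csv
```

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generator and what it does and does not emulate, the numerical choices, and
known limitations.
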