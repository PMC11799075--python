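# Methods

This note documents the models implemented in `gammadt`, the assumptions
they rest on, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Dead-time model

The package implements the paralyzable (extendable) dead-time model: every
arrival at the detector — recorded or not — restarts a dead period of
length τ, so the observed rate in a window is

    R_wo = R_wt · exp(−R_wt · τ_w).

The forward map peaks at `1/(e·τ_w)` when `R_wt = 1/τ_w`; inversion is
performed on the sub-peak branch only (`R_wt·τ_w ≤ 1`) via the principal
branch of the Lambert W function, `R_wt = −W₀(−R_wo·τ_w)/τ_w`. Observed
rates above the peak have no physical solution and raise an error; rates
within float noise (10⁻¹²) of the peak are mapped to the peak rate. The
super-peak root is never returned: it corresponds to a saturated detector
and is inadmissible for correction.

Because the dead period is restarted by *all* arrivals in the full energy
range, the loss inside a narrow analysis window is governed by the
full-window rate λ: the observed window rate is `wf·λ·exp(−λτ)`, so the
window's apparent dead time is `τ_w = τ/wf` exactly when the recorded
spectrum is undistorted. Spectral distortion (pile-up moving recorded
events out of the window) adds loss, which the field summarises by the
scaling law

    τ_w = τ / wf^η,   η ≥ 1.

η is a configuration parameter (default 1.4, the value most published
camera data support; 1.0, 1.6 and 1.83 have also been reported), but the
pipeline additionally *fits* η from its own simulation rather than assuming
it — regression through the origin of `ln(τ_w/τ)` on `ln(1/wf)` across the
three filter configurations. With pile-up disabled the fitted η is
statistically indistinguishable from 1; with pile-up enabled it rises to
≈1.4. Two τ_w estimators are provided, since per-second acquisition data
support either: the per-second closed form `τ_w = ln(R_wt/R_wo)/R_wt`
(used by the pipeline, one sample per second) and a least-squares rate-sweep
estimator `fit_tau` (the decaying-source analogue).

Dead-time loss is computed on TEW-corrected *primary* rates,
`loss(%) = (true − observed)/true × 100`, not on raw window counts.

## Source term

Lu-177 is represented by its six main photon lines (208.4 and 113.0 keV
gammas; 54.6–64.9 keV X-rays), 0.229 photons per decay in total. Beta
particles and the weak 249.7/321 keV gammas are omitted: betas do not reach
the crystal through a collimator, and the minor gammas contribute
negligibly to either the photopeak window or the full-window rate. Other
nuclides can be loaded from a two-column text table.

## Photon physics

Elemental mass-attenuation tables (H, C, O, Na, Al, I, W, Pb) are packaged
on a 20–500 keV grid and interpolated log-log; the K edges of I, W and Pb
are carried as double grid points so interpolation never crosses an edge.
The table values are desk-precision (~1–2%) transcriptions of standard
compilations — adequate because the analysis rests on transmission
*orderings* and rate ratios, not absolute cross sections. Compounds (water,
NaI, tungsten functional paper) use the mass-fraction mixture rule. The
Compton component is computed analytically from the Klein–Nishina total
cross section and the material's electrons per gram; photoelectric
absorption is treated as the non-Compton remainder, and coherent (Rayleigh)
scattering is ignored — a second-order effect for water above ~50 keV.

Filter transmission is narrow-beam: `exp(−(μ/ρ)(E)·ρ·d)`. For 0.5-mm lead
this gives 0.60 at 208 keV and 0.098 at 113 keV; for 1.2-mm TFP, 0.79 and
0.36. Both filters transmit more at 208.4 keV than at any lower Lu-177
line, which is the premise of the whole method.

**TFP density.** The TFP composition is fixed (H 24.2 / C 40.4 / O 20.2 /
W 15.2 mol%, ≈77% tungsten by weight) but its bulk density is a free
parameter of the material model; the packaged default is 3.4 g/cm³.
Sensitivity: the TFP transmission exponent is proportional to ρ·d, so a
±10% density error scales `ln(transmission)` by ±10% (at 208.4 keV,
transmission 0.79 → 0.77/0.81). The default is deliberately *not* tuned to
reproduce any published count-rate ratio; override it in the config if the
areal density of the actual sheet is known.

## Synthetic phantom and transport

The generator replaces a voxel-anatomy Monte Carlo with the simplest
geometry that preserves what the analysis consumes: per-detector incident
spectra with realistic primary/scatter structure and anterior/posterior
asymmetry.

- Body: homogeneous water box, half-sizes (15, 10, 15) cm.
- Organs: liver (ellipsoid, anterior-right, 40 %IA), spleen
  (posterior-left, 4 %IA), two kidneys (posterior, 4 %IA each); 52 %IA
  total at 24 h of a 7.4-GBq administration (3.85 GBq resident). Only the
  52 %IA total is anchored to published whole-body retention; the per-organ
  split is synthetic and models a liver-dominated tumor burden, which is
  why detector 1 (anterior) records higher rates than detector 2
  (posterior).
- Collimator: an ideal angular gate with a 3° acceptance half-angle about
  the detector normal, over a 59.1 × 44.5 cm face at 1 cm standoff. No
  septal penetration, no PSF — absolute sensitivity is therefore arbitrary,
  but spectral shape and all between-configuration ratios are meaningful.
- Transport: decay positions sampled ∝ organ %IA, emission lines ∝
  intensity, isotropic directions; exponential free paths in water;
  at each interaction, Compton scattering with probability μ_C/μ_total
  (else absorption), scattering cosines rejection-sampled from
  Klein–Nishina, up to `max_scatters = 2` orders (the third-order
  contribution to the 167–250 keV region is far below the TEW sub-window
  statistics). Photons below 20.5 keV are terminated.
- Scoring: a forced-detection (next-event) estimator accumulates, at the
  emission point and at every Compton vertex, the probability of reaching
  the detector within the acceptance cone times the attenuation along the
  exit path — unbiased, and ~10³× more efficient than analog scoring
  through a 3.4 × 10⁻⁴ solid-angle fraction. Because the filter acts
  multiplicatively at the exit energy, one transport run scores all three
  filter configurations with identical histories, so filtered vs unfiltered
  spectra are exactly paired (a filter can never increase a bin).

What the generator does **not** emulate: voxel anatomy, collimator septal
X-rays and penetration (a major low-energy component in real cameras — our
window fractions are therefore higher than camera-measured ones),
backscatter from structures behind the crystal, room scatter, and
Rayleigh scattering. Consequently, passing tests demonstrate the internal
consistency of the dead-time/TEW machinery and the direction and rough
magnitude of filter effects — not absolute agreement with any particular
camera.

## Detector response

Interacting photons (probability `1 − exp(−μ_NaI·d)`, 9.5-mm crystal) are
assumed to deposit their full energy; crystal Compton escape is folded into
the blur rather than modelled. Energy resolution is Gaussian with FWHM
fraction `0.094·(E/208.4)^(−1/2)` — anchored at the published photopeak
value, with the standard inverse-square-root scaling of scintillator
statistics (the exponent is configurable). Arrivals form a homogeneous
Poisson stream at the detected rate; the paralyzable filter then records an
event only when the gap since the previous arrival exceeds τ (0.5 µs for
the full 20–400 keV window). With pile-up enabled (the default), unrecorded
arrivals within one integration time (= τ by default) of a recorded event
add their energy to it, producing the spectral distortion that drives
η > 1. Whether a real camera's dead-time electronics behave closer to the
pile-up-on or pile-up-off idealisation is camera-specific; the switch
brackets the possibilities.

Acquisition follows the stop rule *simulate whole seconds until the
cumulative observed main-window counts exceed 10,000* (minimum one
second). The orchestrated experiment additionally imposes a five-second
floor so that per-second statistics (means, SDs, Welch tests) rest on at
least n = 5 — at the count rates of this geometry the 10-kcount rule alone
is often satisfied within one second.

## Spectroscopy

The analysis window is the photopeak ±10% ([187.56, 229.24] keV for
208.4 keV; a nominal-208 variant gives [187.2, 228.8]). TEW sub-windows
abut the main window; the quoted "10%" sub-window width is interpreted as
10% of the photopeak energy (20.84 keV) by default, with 10% of the
main-window width selectable, since both readings circulate. Scatter under
the peak is the trapezoid `S = (C_L/w_L + C_U/w_U)·w_M/2`; primary counts
are clamped at zero with a flag. Sub-window counts are taken from the
observed (post-dead-time) spectrum, as a real camera must; the loss-free
reference uses the unscattered component of the true arrival stream
directly, which the event generator tags per event.

## Time-course assessment

True count rates at t ≥ 24 h scale from the simulated 24-h rates by the
retention curve, `R(t) = R₂₄·ret(t)/ret(24)`; observed rates follow the
forward paralyzable model with the per-configuration apparent dead time
held fixed over time (window fractions drift little over 24–120 h, and the
published analyses make the same approximation). The default retention
curve is a synthetic slow-excretion stand-in: mono-exponential with an
80-h effective half-life normalised to 52 %IA at 24 h (Lu-177's physical
half-life is 161 h; 80 h effective corresponds to moderate biological
clearance on top of decay, the regime where late-time dead-time loss stays
worst). Tabulated curves are accepted for real patient data.
`small_loss_ratio` implements the first-order limit
`loss₁/loss₂ ≈ (R₁τ₁)/(R₂τ₂)` used to summarise loss ratios in the 1–5%
loss regime.

## Statistics

Per-second window fractions, apparent dead times, primary rates and losses
are compared between each filter and the unfiltered acquisition with
Welch's unequal-variance t-test (two-sided, α = 0.05), Bonferroni-corrected
within each metric family (m = 2 filters × 2 detectors = 4). The report
records m.

## Numerical and reproducibility choices

- One seed drives everything through `numpy.random.SeedSequence` spawning:
  two transport streams (one per detector) then one measurement stream per
  (detector, filter). The same seed reproduces a report byte for byte.
- Default problem sizes: 150,000 transport histories per detector and
  ≥5 simulated seconds per configuration — a full comparison runs in about
  ten seconds on one core, with per-second SDs comfortably below the
  between-configuration differences.
- Energy bins are 1 keV over 20–500 keV; window counts are taken from raw
  event energies, not the binned spectra, so window edges need not align
  with bins.
- The Klein–Nishina sampler uses plain rejection under the forward-peak
  envelope (acceptance ≈ 45–75% over 20–500 keV); the closed-form total
  cross section is verified against numerical integration in the tests.
- Per-second τ_w estimates are undefined for seconds with zero counts and
  are excluded (NaN) rather than propagated.

## Known limitations

- Absolute count rates, window fractions and apparent dead times depend on
  the simplified geometry (no collimator physics, full-energy deposition),
  so they differ from camera-measured values; only orderings, the η ≈ 1.4
  emergence, and the dead-time arithmetic are quantitative.
- The TFP bulk density is uncertain at the ±10% level (see above).
- The paralyzable model is assumed exact; real cameras mix paralyzable and
  non-paralyzable behaviour at very high rates.
- Organ %IA values and the retention curve are synthetic stand-ins, clearly
  labelled as such; users studying real patients should supply their own.
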