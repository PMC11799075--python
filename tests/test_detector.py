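from dataclasses import replace

import numpy as np
import pytest

from gammadt.detector import (
    DetectorConfig,
    EventStream,
    apply_paralyzable,
    blur_energy,
    fwhm_fraction,
    generate_event_stream,
    intrinsic_efficiency,
    record_measurement,
)
from gammadt.phantom import IncidentSpectrum

CFG = DetectorConfig()


def flat_spectrum(rate_per_bin, lo=180.0, hi=240.0, scatter_share=0.0):
    """A uniform incident spectrum confined to [lo, hi) keV."""
    edges = np.arange(20.0, 501.0, 1.0)
    prim = np.zeros(edges.size - 1)
    mask = (edges[:-1] >= lo) & (edges[:-1] < hi)
    prim[mask] = rate_per_bin
    scat = prim * scatter_share / (1 - scatter_share) if scatter_share else np.zeros_like(prim)
    return IncidentSpectrum(edges, prim, scat)


class TestIntrinsicEfficiency:
    def test_zero_thickness(self):
        cfg = replace(CFG, crystal_thickness_cm=0.0)
        assert intrinsic_efficiency(208.4, cfg) == 0.0

    def test_saturates_at_low_energy(self):
        assert intrinsic_efficiency(30.0, CFG) > 0.999

    def test_photopeak_value_matches_hand_computation(self):
        # 1 - exp(-mu/rho * 3.67 * 0.95) with the packaged Na/I tables
        assert intrinsic_efficiency(208.4, CFG) == pytest.approx(0.68226, rel=1e-4)


class TestEnergyBlur:
    def test_sigma_at_photopeak(self):
        # FWHM 9.4% of 208.4 keV -> sigma = 8.319 keV
        draws = blur_energy(np.full(1_000_000, 208.4), CFG, seed=1)
        assert np.std(draws) == pytest.approx(8.319, rel=0.01)
        assert np.mean(draws) == pytest.approx(208.4, abs=0.05)

    def test_zero_width_is_identity(self):
        cfg = replace(CFG, resolution_fwhm=1e-15)
        assert blur_energy(113.0, cfg, seed=2) == pytest.approx(113.0, abs=1e-9)

    def test_resolution_scaling_law(self):
        # FWHM fraction ~ 1/sqrt(E): 12.8% at 113 keV
        assert fwhm_fraction(113.0, CFG) == pytest.approx(0.12765, rel=1e-4)

    def test_draws_stay_positive(self):
        cfg = replace(CFG, resolution_fwhm=1.5)  # pathologically wide
        draws = blur_energy(np.full(10_000, 30.0), cfg, seed=3)
        assert np.all(draws > 0)


class TestEventStream:
    def test_poisson_count(self):
        spec = flat_spectrum(2000.0)  # ~60 bins -> large rate
        stream = generate_event_stream(spec, CFG, 1.0, seed=4)
        lam = float((spec.total * np.asarray(intrinsic_efficiency(spec.centers, CFG))).sum())
        assert abs(len(stream) - lam) < 3 * np.sqrt(lam)

    def test_blur_conserves_counts(self):
        spec = flat_spectrum(500.0)
        stream = generate_event_stream(spec, CFG, 1.0, seed=5)
        assert stream.energies.size == stream.times.size == len(stream)

    def test_zero_spectrum_empty_stream(self):
        spec = flat_spectrum(0.0)
        assert len(generate_event_stream(spec, CFG, 1.0, seed=6)) == 0

    def test_deterministic(self):
        spec = flat_spectrum(100.0)
        a = generate_event_stream(spec, CFG, 1.0, seed=7)
        b = generate_event_stream(spec, CFG, 1.0, seed=7)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.energies, b.energies)


class TestParalyzable:
    def test_zero_tau_identity(self):
        s = EventStream(np.array([0.0, 1.0]), np.array([100.0, 200.0]))
        out = apply_paralyzable(s, 0.0)
        assert np.array_equal(out.times, s.times)

    def test_analytic_loss_rate(self):
        # recorded rate = lambda exp(-lambda tau) for Poisson arrivals
        lam, tau, dur = 1e5, 5e-7, 20.0
        rng = np.random.default_rng(8)
        n = rng.poisson(lam * dur)
        t = np.sort(rng.uniform(0, dur, n))
        s = EventStream(t, np.full(n, 208.0))
        out = apply_paralyzable(s, tau)
        expected = lam * np.exp(-lam * tau) * dur
        assert abs(len(out) - expected) < 3 * np.sqrt(expected)

    def test_two_close_arrivals(self):
        tau = 1e-6
        s = EventStream(np.array([0.0, 0.3e-6]), np.array([100.0, 50.0]))
        out = apply_paralyzable(s, tau, pileup=False)
        assert len(out) == 1 and out.energies[0] == 100.0
        piled = apply_paralyzable(s, tau, pileup=True)
        assert len(piled) == 1 and piled.energies[0] == pytest.approx(150.0)

    def test_pileup_sums_all_window_arrivals(self):
        tau = 1e-6
        s = EventStream(
            np.array([0.0, 0.3e-6, 0.6e-6]), np.array([100.0, 50.0, 25.0])
        )
        piled = apply_paralyzable(s, tau, pileup=True)
        assert len(piled) == 1
        assert piled.energies[0] == pytest.approx(175.0)

    def test_subwindow_apparent_deadtime_scales_with_wf(self):
        # without pile-up, tau_w of a sub-window = tau / wf
        lam, tau, dur, wf = 2e5, 5e-7, 30.0, 0.25
        rng = np.random.default_rng(9)
        n = rng.poisson(lam * dur)
        t = np.sort(rng.uniform(0, dur, n))
        e = np.where(rng.uniform(size=n) < wf, 208.0, 100.0)
        s = EventStream(t, e)
        out = apply_paralyzable(s, tau)
        r_true = (e == 208.0).sum() / dur
        r_obs = (out.energies == 208.0).sum() / dur
        tau_w = np.log(r_true / r_obs) / r_true
        assert tau_w == pytest.approx(tau / wf, rel=0.05)

    def test_negative_tau_rejected(self):
        s = EventStream(np.array([0.0]), np.array([100.0]))
        with pytest.raises(ValueError):
            apply_paralyzable(s, -1e-6)


class TestRecordMeasurement:
    # wide main window so the Gaussian blur keeps essentially all counts
    WINDOWS = {"main": (120.0, 320.0), "full": (20.0, 400.0)}

    def test_stop_rule_expected_duration(self):
        # observed main rate ~5000/s -> >10k cumulative at second 2 or 3
        spec = flat_spectrum(5000.0 / 60.0)
        cfg = replace(CFG, tau_full_s=0.0, crystal_thickness_cm=1e3)  # eff ~1
        m = record_measurement(spec, cfg, self.WINDOWS, seed=10)
        assert m.duration_s in (2, 3)

    def test_huge_rate_single_second(self):
        spec = flat_spectrum(2e4)
        m = record_measurement(spec, CFG, self.WINDOWS, seed=11)
        assert m.duration_s == 1

    def test_losses_only_in_totals(self):
        spec = flat_spectrum(3e3, scatter_share=0.3)
        m = record_measurement(spec, CFG, self.WINDOWS, seed=12)
        true_full = m.counts("full", "true")
        obs_full = m.counts("full", "observed")
        assert np.all(obs_full <= true_full)

    def test_unreachable_target_errors(self):
        spec = flat_spectrum(1.0)
        with pytest.raises(RuntimeError):
            record_measurement(spec, CFG, self.WINDOWS, seed=13, max_seconds=3)

    def test_min_seconds_floor(self):
        spec = flat_spectrum(2e4)
        m = record_measurement(spec, CFG, self.WINDOWS, seed=14, min_seconds=4)
        assert m.duration_s == 4
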