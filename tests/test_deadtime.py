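import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gammadt.deadtime import (
    CountRatePair,
    ParalyzableDeadTimeModel,
    WindowScalingModel,
    apparent_dead_time,
    apparent_dead_time_single,
    deadtime_loss,
    eta_single,
    fit_eta,
    fit_tau,
    paralyzable_observed,
    paralyzable_true,
)


class TestForwardModel:
    def test_low_rate_loss_regime(self):
        # 1.1 kcps true with a 9.3 us apparent dead time -> 1.09 kcps observed
        assert paralyzable_observed(1.1e3, 9.3e-6) == pytest.approx(1088.8, abs=0.1)

    def test_upper_rate_loss_regime(self):
        assert paralyzable_observed(5.6e3, 9.3e-6) == pytest.approx(5315.8, abs=0.1)

    def test_zero_rate(self):
        assert paralyzable_observed(0.0, 1e-5) == 0.0

    def test_maximum_at_inverse_tau(self):
        tau = 9.3e-6
        peak = paralyzable_observed(1 / tau, tau)
        assert peak == pytest.approx(1 / (np.e * tau), rel=1e-12)
        eps = 1.0
        assert paralyzable_observed(1 / tau - eps, tau) < peak
        assert paralyzable_observed(1 / tau + eps, tau) < peak


class TestInverseModel:
    def test_round_trip(self):
        assert paralyzable_true(1088.80436, 9.3e-6) == pytest.approx(1.1e3, rel=1e-6)

    def test_zero(self):
        assert paralyzable_true(0.0, 9.3e-6) == 0.0

    def test_boundary_closed_form(self):
        tau = 2e-6
        assert paralyzable_true(1 / (np.e * tau), tau) == pytest.approx(1 / tau, rel=1e-9)

    def test_unphysical_rate_rejected(self):
        with pytest.raises(ValueError):
            paralyzable_true(1.01 / (np.e * 2e-6), 2e-6)

    @given(
        st.floats(min_value=1e-7, max_value=1e-5),
        st.floats(min_value=0.0, max_value=0.99),
    )
    def test_round_trip_on_physical_branch(self, tau, frac):
        r_true = frac / tau  # R tau <= 0.99 < 1: sub-peak branch
        r_obs = paralyzable_observed(r_true, tau)
        back = paralyzable_true(r_obs, tau)
        assert back == pytest.approx(r_true, rel=1e-10, abs=1e-10)


class TestWindowScaling:
    def test_full_window_identity(self):
        assert apparent_dead_time(0.5e-6, 1.0, 1.7) == pytest.approx(0.5e-6)

    def test_linear_eta(self):
        assert apparent_dead_time(0.5e-6, 0.12, 1.0) == pytest.approx(4.1667e-6, rel=1e-4)

    def test_camera_typical_eta(self):
        # eta = 1.4 with wf = 0.12 lands between the simulated 8.7-9.8 us
        tw = apparent_dead_time(0.5e-6, 0.12, 1.4)
        assert tw == pytest.approx(9.730e-6, rel=1e-4)
        assert 8.7e-6 < tw < 9.8e-6

    def test_zero_wf_rejected(self):
        with pytest.raises(ValueError):
            apparent_dead_time(0.5e-6, 0.0, 1.4)

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_strictly_decreasing_in_wf(self, wf):
        t1 = apparent_dead_time(0.5e-6, wf, 1.4)
        t2 = apparent_dead_time(0.5e-6, min(wf * 1.1, 1.0), 1.4)
        assert t2 < t1


class TestLoss:
    def test_no_loss(self):
        assert deadtime_loss(100.0, 100.0) == 0.0

    def test_five_percent(self):
        assert deadtime_loss(100.0, 95.0) == pytest.approx(5.0)

    def test_printed_upper_rate(self):
        obs = paralyzable_observed(5.6e3, 9.3e-6)
        assert deadtime_loss(5.6e3, obs) == pytest.approx(5.07, abs=0.01)

    def test_zero_true_rate_undefined(self):
        with pytest.raises(ValueError):
            deadtime_loss(0.0, 0.0)

    def test_loss_increasing_in_rate_below_peak(self):
        tau = 9.3e-6
        rates = np.linspace(100, 0.9 / tau, 50)
        losses = deadtime_loss(rates, paralyzable_observed(rates, tau))
        assert np.all(np.diff(losses) > 0)


class TestFitTau:
    def test_noiseless_recovery(self):
        tau = 9.3e-6
        r = np.linspace(1e3, 2e4, 12)
        pairs = [CountRatePair(x, paralyzable_observed(x, tau)) for x in r]
        est, se = fit_tau(pairs)
        assert est == pytest.approx(tau, rel=1e-12)

    def test_poisson_noised_recovery_within_2_percent(self):
        tau = 9.3e-6
        rng = np.random.default_rng(5)
        r_true = np.linspace(1e3, 2e4, 12)
        n_per_point = 1e5
        exposure = n_per_point / (r_true * np.exp(-r_true * tau))
        counts = rng.poisson(r_true * np.exp(-r_true * tau) * exposure)
        r_obs = counts / exposure
        est, se = fit_tau((r_true, r_obs))
        assert est == pytest.approx(tau, rel=0.02)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_tau([CountRatePair(1e3, 900.0), CountRatePair(1e3, 905.0)])

    def test_single_pair_solver(self):
        tau = 4e-6
        r = 2e4
        assert apparent_dead_time_single(r, paralyzable_observed(r, tau)) == pytest.approx(
            tau, rel=1e-12
        )


class TestFitEta:
    def test_noiseless_recovery(self):
        tau = 0.5e-6
        wf = np.array([0.12, 0.18, 0.31, 0.6])
        tw = apparent_dead_time(tau, wf, 1.4)
        assert fit_eta(wf, tw, tau) == pytest.approx(1.4, rel=1e-12)

    def test_published_window_fractions_give_eta_near_1p4(self):
        # detector-1 style values: wf {0.12, 0.18, 0.31}, tau_w {8.7, 5.6, 2.9} us
        eta = fit_eta([0.12, 0.18, 0.31], np.array([8.7, 5.6, 2.9]) * 1e-6, 0.5e-6)
        assert eta == pytest.approx(1.392, abs=0.005)

    def test_single_pair_closed_form(self):
        assert eta_single(0.12, 8.7e-6, 0.5e-6) == pytest.approx(1.347, abs=0.001)

    def test_full_window_inconsistency_flagged(self):
        with pytest.raises(ValueError):
            fit_eta([1.0, 0.5], [2e-6, 1e-6], 0.5e-6)


class TestModelObjects:
    def test_ols_results(self):
        tau = 6e-6
        r = np.linspace(2e3, 3e4, 10)
        model = ParalyzableDeadTimeModel(r, paralyzable_observed(r, tau))
        res = model.fit()
        assert res.tau_w == pytest.approx(tau, rel=1e-10)
        assert res.nobs == 10
        assert "tau_w" in res.summary()
        assert res.correct(res.predict(1e4)) == pytest.approx(1e4, rel=1e-9)

    def test_single_method_matches_ols_on_exact_data(self):
        tau = 6e-6
        r = np.linspace(2e3, 3e4, 10)
        model = ParalyzableDeadTimeModel(r, paralyzable_observed(r, tau))
        assert model.fit("single").tau_w == pytest.approx(tau, rel=1e-10)

    def test_from_dataframe(self):
        tau = 3e-6
        r = np.linspace(1e3, 1e4, 5)
        df = pd.DataFrame({"true_rate": r, "observed_rate": paralyzable_observed(r, tau)})
        res = ParalyzableDeadTimeModel.from_dataframe(df).fit()
        assert res.tau_w == pytest.approx(tau, rel=1e-10)

    def test_window_scaling_summary(self):
        tau = 0.5e-6
        wf = np.array([0.1, 0.2, 0.4])
        res = WindowScalingModel(wf, apparent_dead_time(tau, wf, 1.6), tau).fit()
        assert res.eta == pytest.approx(1.6, rel=1e-12)
        assert "eta" in res.summary()

    def test_count_rate_pair_validation(self):
        with pytest.raises(ValueError):
            CountRatePair(100.0, 200.0)
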