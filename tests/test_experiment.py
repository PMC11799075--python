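import numpy as np
import pandas as pd
import pytest

from gammadt.experiment import (
    ExperimentConfig,
    bonferroni,
    default_experiment_config,
    rebuild_report,
    run_experiment,
    welch_t,
)


def small_config() -> ExperimentConfig:
    cfg = default_experiment_config()
    cfg.n_histories = 15_000
    cfg.min_seconds = 2
    cfg.timecourse_grid_h = (24.0, 72.0, 120.0)
    return cfg


@pytest.fixture(scope="module")
def small_report():
    return run_experiment(small_config(), seed=99)


class TestWelch:
    def test_identical_samples(self):
        stat, p = welch_t([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_strongly_shifted_gaussians(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(5.0, 1.0, 30)
        _, p = welch_t(a, b)
        assert p < 1e-6

    def test_sample_size_validation(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [3.0, 3.0])


class TestBonferroni:
    def test_basic_scaling(self):
        assert bonferroni([0.01], 3) == pytest.approx([0.03])

    def test_capped_at_one(self):
        assert bonferroni([0.5], 4) == pytest.approx([1.0])

    def test_zero_stays_zero(self):
        assert bonferroni([0.0], 10) == pytest.approx([0.0])

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)


class TestRunExperiment:
    def test_deterministic_for_fixed_seed(self):
        cfg = small_config()
        a = run_experiment(cfg, seed=5)
        b = run_experiment(cfg, seed=5)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        pd.testing.assert_frame_equal(a.per_second, b.per_second)
        assert a.summary_text() == b.summary_text()

    def test_window_fraction_ordering(self, default_report):
        summ = default_report.summary.set_index(["config", "detector"])
        for det in (1, 2):
            assert (
                summ.loc[("lead", det), "wf_mean"]
                > summ.loc[("tfp", det), "wf_mean"]
                > summ.loc[("none", det), "wf_mean"]
            )

    def test_apparent_dead_time_ordering(self, default_report):
        summ = default_report.summary.set_index(["config", "detector"])
        for det in (1, 2):
            assert (
                summ.loc[("lead", det), "tau_w_us_mean"]
                < summ.loc[("tfp", det), "tau_w_us_mean"]
                < summ.loc[("none", det), "tau_w_us_mean"]
            )

    def test_loss_ordering(self, default_report):
        summ = default_report.summary.set_index(["config", "detector"])
        for det in (1, 2):
            assert (
                summ.loc[("none", det), "loss_percent_mean"]
                > summ.loc[("tfp", det), "loss_percent_mean"]
                > summ.loc[("lead", det), "loss_percent_mean"]
            )

    def test_bonferroni_relation_in_report(self, default_report):
        comp = default_report.comparisons
        m = default_report.n_comparisons
        assert np.allclose(comp["p_adj"], np.minimum(1.0, comp["p_raw"] * m))

    def test_filters_significantly_change_window_fraction(self, default_report):
        comp = default_report.comparisons
        wf = comp[comp.metric == "wf"]
        assert (wf["p_adj"] < 0.05).all()


class TestReportArtifacts:
    def test_save_writes_all_csvs(self, small_report, tmp_path):
        small_report.save(tmp_path)
        for name in (
            "per_second.csv",
            "summary.csv",
            "comparisons.csv",
            "eta.csv",
            "timecourse.csv",
            "loss_ratios.csv",
            "summary.txt",
        ):
            assert (tmp_path / name).exists()
        assert (tmp_path / "spectrum_lead_det2.csv").exists()

    def test_rebuild_from_per_second_reproduces_summary(self, small_report, tmp_path):
        small_report.save(tmp_path)
        cfg = small_config()
        summary, eta = rebuild_report(tmp_path / "per_second.csv", cfg)
        pd.testing.assert_frame_equal(
            summary.reset_index(drop=True),
            small_report.summary.reset_index(drop=True),
            check_dtype=False,
        )
        pd.testing.assert_frame_equal(
            eta.reset_index(drop=True),
            small_report.eta.reset_index(drop=True),
            check_dtype=False,
        )

    def test_timecourse_losses_consistent(self, small_report):
        tc = small_report.timecourse
        expected = (tc.true_rate - tc.observed_rate) / tc.true_rate * 100
        assert np.allclose(tc.loss_percent, expected, rtol=1e-10)


class TestConfigIO:
    def test_packaged_default_yaml_round_trip(self):
        from importlib import resources

        path = str(resources.files("gammadt").joinpath("data/default_config.yaml"))
        cfg = ExperimentConfig.from_yaml(path)
        ref = default_experiment_config()
        assert cfg.phantom.total_percent_ia == ref.phantom.total_percent_ia
        assert cfg.detector.tau_full_s == pytest.approx(5e-7)
        assert cfg.filters["lead"].thickness_cm == pytest.approx(0.05)
        assert cfg.filters["tfp"].material.density == pytest.approx(3.4)
        assert cfg.tew.main.low == pytest.approx(187.56)
        assert cfg.retention(24.0) == pytest.approx(0.52)

    def test_from_dict_overrides(self):
        cfg = ExperimentConfig.from_dict(
            {
                "detector_response": {"tau_full_us": 1.0, "pileup": False},
                "run": {"n_histories": 1234},
                "filters": {"none": None, "lead": {"material": "lead", "thickness_mm": 1.0}},
            }
        )
        assert cfg.detector.tau_full_s == pytest.approx(1e-6)
        assert not cfg.detector.pileup
        assert cfg.n_histories == 1234
        assert cfg.filters["lead"].thickness_cm == pytest.approx(0.1)


class TestCLI:
    def test_deadtime_calculator_forward(self):
        from click.testing import CliRunner

        from gammadt.cli import main

        r = CliRunner().invoke(
            main, ["deadtime", "--tau-us", "9.3", "--mode", "forward", "--rate", "5600"]
        )
        assert r.exit_code == 0
        assert float(r.output.strip()) == pytest.approx(5315.8, abs=0.1)

    def test_deadtime_calculator_inverse_round_trip(self):
        from click.testing import CliRunner

        from gammadt.cli import main

        r = CliRunner().invoke(
            main, ["deadtime", "--tau-us", "9.3", "--mode", "inverse", "--rate", "5315.816"]
        )
        assert r.exit_code == 0
        assert float(r.output.strip()) == pytest.approx(5600.0, rel=1e-4)

    def test_timecourse_command(self, tmp_path):
        from click.testing import CliRunner

        from gammadt.cli import main

        out = tmp_path / "tc.csv"
        r = CliRunner().invoke(
            main, ["timecourse", "--r24", "12600", "--tau-us", "9.3", "--out", str(out)]
        )
        assert r.exit_code == 0
        df = pd.read_csv(out)
        assert df.loss_percent.iloc[0] > df.loss_percent.iloc[-1]
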