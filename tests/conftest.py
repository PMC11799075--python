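import pytest
from hypothesis import HealthCheck, settings

import gammadt as g

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lu177():
    return g.default_lu177_lines()


@pytest.fixture(scope="session")
def lead_filter():
    return g.FilterSpec(g.lead(), 0.05)  # 0.5 mm


@pytest.fixture(scope="session")
def tfp_filter():
    return g.FilterSpec(g.tungsten_functional_paper(), 0.12)  # 1.2 mm


@pytest.fixture(scope="session")
def default_report():
    """One full default experiment run shared by ordering/regression tests."""
    cfg = g.default_experiment_config()
    return g.run_experiment(cfg, seed=1337)


@pytest.fixture(scope="session")
def report_pileup_off():
    """Same experiment with pile-up summation disabled."""
    from dataclasses import replace

    cfg = g.default_experiment_config()
    cfg.n_histories = 100_000
    cfg.detector = replace(cfg.detector, pileup=False)
    return g.run_experiment(cfg, seed=1337)
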