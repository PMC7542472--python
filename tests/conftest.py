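import dataclasses

import pytest

import tumorshed as ts


@pytest.fixture(scope="session")
def default_cfg() -> ts.ModelConfig:
    return ts.make_fixture_config("defaults")


@pytest.fixture(scope="session")
def baseline_cfg(default_cfg) -> ts.ModelConfig:
    """Defaults with the selected vascularization rate of the reference run."""
    return dataclasses.replace(
        default_cfg,
        vascular=dataclasses.replace(default_cfg.vascular, k_v=0.1005),
    )


@pytest.fixture(scope="session")
def default_rates(default_cfg) -> ts.CompartmentRates:
    return ts.compartment_rate_table(
        default_cfg.spatial, default_cfg.oxygen, default_cfg.anchors
    )


@pytest.fixture(scope="session")
def short_growth(baseline_cfg) -> ts.GrowthTrajectory:
    """A 2000-day baseline run shared by shedding/experiment tests."""
    return ts.run_growth(baseline_cfg, t_end=2000)


@pytest.fixture(scope="session")
def baseline_growth_12y(baseline_cfg) -> ts.GrowthTrajectory:
    """The full 12-year reference growth run (computed once per session)."""
    return ts.run_growth(baseline_cfg)
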