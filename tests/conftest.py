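import pytest

import corsurvey as cs
from corsurvey.derive import derive_indicators
from corsurvey.simulate import SurveyDataset


@pytest.fixture(scope="session")
def default_cfg():
    return cs.default_config()


@pytest.fixture(scope="session")
def small_cfg(default_cfg):
    """Default conditions at a reduced sample size for cheap structural tests."""
    cfg = default_cfg.copy()
    cfg.n_sampled = 8000
    return cfg


@pytest.fixture(scope="session")
def sim_default(default_cfg):
    """One full-size simulated survey (seed 1), shared across tests."""
    return cs.simulate_survey(default_cfg, seed=1)


@pytest.fixture(scope="session")
def derived_default(sim_default):
    """The seed-1 survey with indicators and contact groups derived."""
    return SurveyDataset(frame=derive_indicators(sim_default.frame), truth=sim_default.truth)
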