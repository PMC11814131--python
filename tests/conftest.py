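import numpy as np
import pandas as pd
import pytest

from mhwbloom import ScenarioConfig, build_climatology, generate_sst


@pytest.fixture(scope="session")
def null_scenario():
    """Event-free 20-year scenario at the generator defaults."""
    cfg = ScenarioConfig(n_years=20, start_year=1990, seed=7)
    sst, truth = generate_sst(cfg)
    return cfg, sst, truth


@pytest.fixture(scope="session")
def null_climatology(null_scenario):
    cfg, sst, _ = null_scenario
    return build_climatology(
        sst, (1990, 2009), percentiles=(8.0, 10.0, 90.0, 92.0), variable="sst"
    )


@pytest.fixture(scope="session")
def flat_climatology():
    """Climatology of a constant series: every slot mean 20, sd 0, thresholds 20."""
    dates = pd.date_range("2000-01-01", "2004-12-31", freq="D")
    series = pd.Series(20.0, index=dates)
    return build_climatology(series, (2000, 2004), percentiles=(10.0, 90.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
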