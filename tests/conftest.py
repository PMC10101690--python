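import datetime as dt

import numpy as np
import pandas as pd
import pytest

from treeflux.config import PipelineConfig, SimulationConfig
from treeflux import synthetic as syn


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Default-season simulation config used by generator tests."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def env(sim_config):
    return syn.simulate_environment(sim_config)


@pytest.fixture(scope="session")
def truth(env, sim_config):
    return syn.simulate_true_fluxes(env, sim_config)


def short_pipeline_config(seed: int = 3, outdir: str = "scratch_test") -> PipelineConfig:
    """A reduced-closure, short-season pipeline config for integration tests."""
    cfg = PipelineConfig(seed=seed, outdir=outdir)
    # order matters: keep the dry window inside the season at every step
    cfg.simulation.season_start = dt.date(2018, 5, 1)
    cfg.simulation.dry_start = dt.date(2018, 8, 1)
    cfg.simulation.dry_end = dt.date(2018, 8, 20)
    cfg.simulation.season_end = dt.date(2018, 9, 10)
    cfg.simulation.chambers["shoot"].closures_per_day = 10
    cfg.simulation.chambers["stem"].closures_per_day = 10
    cfg.simulation.chambers["soil"].closures_per_day = 4
    cfg.coherence.n_surrogates = 100
    cfg.coherence.max_period_days = 32.0
    return cfg


@pytest.fixture()
def daily_dates():
    return pd.date_range("2018-05-01", periods=160, freq="D")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
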