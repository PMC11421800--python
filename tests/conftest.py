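import numpy as np
import pandas as pd
import pytest

from microcq import SimulationConfig, simulate_campaign


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic campaign at the default study settings."""
    return simulate_campaign(SimulationConfig(rng_seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced campaign (fewer taxa, smaller libraries) for fast tests."""
    config = SimulationConfig(
        rng_seed=11,
        n_core_taxa=40,
        n_event_taxa=10,
        library_size_range=(5000, 8000),
    )
    return simulate_campaign(config)


@pytest.fixture()
def flat_hydro():
    """Constant-baseflow hydrograph helper."""
    dates = pd.date_range("2020-10-06", periods=6, freq="D")
    return pd.DataFrame(
        {"discharge_cms": np.full(6, 0.25), "precip_mm": np.zeros(6)}, index=dates
    )


def make_hydro(q, start="2020-10-06"):
    q = np.asarray(q, dtype=float)
    dates = pd.date_range(start, periods=len(q), freq="D")
    return pd.DataFrame(
        {"discharge_cms": q, "precip_mm": np.zeros(len(q))}, index=dates
    )
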