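import pytest

import leafwind as lw


@pytest.fixture(scope="session")
def tomato():
    return lw.load_preset("tomato_greenhouse")


@pytest.fixture(scope="session")
def wheat():
    return lw.load_preset("wheat_field")


@pytest.fixture(scope="session")
def diurnal_result():
    """Full 16 h diurnal greenhouse run at the four standard gbw levels
    (shared: this is the most expensive simulation in the suite)."""
    return lw.run_diurnal(dt=2.0)


@pytest.fixture(scope="session")
def sweep_result():
    """Full ambient-CO2 x gbw sweep (11 x 9 grid, batched integration)."""
    return lw.run_sweep(dt=2.0)


@pytest.fixture(scope="session")
def profile_result():
    """Steady-state wheat-canopy profile for two leaf sizes + infinite gb."""
    return lw.run_profile()
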