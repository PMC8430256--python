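import numpy as np
import pytest

from cardioemd import (
    MechParameters,
    SimulationConfig,
    run_protocol,
    run_twitch,
)


@pytest.fixture(scope="session")
def normal_traces():
    """Final-beat traces of the normal (all-100 %) case at both BCLs."""
    return run_protocol(None, SimulationConfig())


@pytest.fixture(scope="session")
def normal_twitch_600(normal_traces):
    return run_twitch(normal_traces[600.0], MechParameters())


@pytest.fixture(scope="session")
def normal_twitch_1000(normal_traces):
    return run_twitch(normal_traces[1000.0], MechParameters())


@pytest.fixture(scope="session")
def normal_records():
    """Biomarker records of the normal case at both BCLs."""
    from cardioemd import run_case_pair
    return run_case_pair(None)


@pytest.fixture(scope="session")
def fast_config():
    """Cheap configuration for machinery tests (1 beat, one BCL, no mech)."""
    return SimulationConfig(n_beats=1, bcl_ms=(600.0,))
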