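import numpy as np
import pytest

from glucoge import (ScenarioConfig, VirtualPatientParams, load_default_grammar,
                     simulate_patient)


@pytest.fixture(scope="session")
def grammar():
    return load_default_grammar()


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def patient14(scenario):
    """A 14-day virtual patient with default physiology, fixed seed."""
    return simulate_patient(VirtualPatientParams(), scenario, seed=42)


@pytest.fixture(scope="session")
def patient3():
    """A short 3-day patient for fast signal-level tests."""
    return simulate_patient(VirtualPatientParams(), ScenarioConfig(days=3), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
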