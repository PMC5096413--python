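import numpy as np
import pytest

from lightplate import CalibrationTable, DeviceConfig


@pytest.fixture(scope="session")
def device():
    """Green-LED plate with one-minute frames (keeps programs small)."""
    return DeviceConfig.uniform(timestep_ms=60_000)


@pytest.fixture(scope="session")
def identity_calib():
    return CalibrationTable.identity()


@pytest.fixture
def rng():
    return np.random.default_rng(20160913)
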