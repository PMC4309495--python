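import numpy as np
import pytest
from hypothesis import settings

from oligono import DonorSpec, MediumSpec, VesselSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# The standard study scenario: DETA/NO in an air-equilibrated 1.3 cm well
# with 0.35 mL of medium.


@pytest.fixture
def deta_10nM():
    return DonorSpec("DETA/NO", 10e-9, 20 * 3600.0, 2.0)


@pytest.fixture
def deta_3nM():
    return DonorSpec("DETA/NO", 3e-9, 20 * 3600.0, 2.0)


@pytest.fixture
def medium():
    return MediumSpec()


@pytest.fixture
def well():
    return VesselSpec(volume=0.35, well_diameter=1.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
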