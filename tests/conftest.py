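import numpy as np
import pytest

from protonfilm import (
    BeamTruth,
    KineticsTruth,
    NoiseSpec,
    preset_truth,
    simulate_calibration_dataset,
)

#: Reference biexponential fixture used across the kinetics tests:
#: netOD_inf=0.4, C1=0.05, T1=1 h, C2=0.03, T2=12 h.
KINETICS_FIXTURE = (0.4, 0.05, 1.0, 0.03, 12.0)


@pytest.fixture(scope="session")
def b1_truth():
    return preset_truth("B1")


@pytest.fixture(scope="session")
def noiseless_b1_dataset(b1_truth):
    """Full noiseless pipeline run over the standard 18-point dose ladder."""
    return simulate_calibration_dataset(b1_truth, noise=NoiseSpec.noiseless())


@pytest.fixture(scope="session")
def kinetics_fixture_truth():
    return KineticsTruth(channels={ch: KINETICS_FIXTURE for ch in ("red", "green", "blue")})


@pytest.fixture()
def beam():
    return BeamTruth()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
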