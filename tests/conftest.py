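import numpy as np
import pytest

from vfret import AcousticDrive, DonorParticle, EstimationProtocol, FluidMedium

WATER_MU = 0.89e-3   # dynamic viscosity of water [Pa*s]
BLOOD_MU = 3.5e-3    # mid-range whole-blood viscosity [Pa*s]


@pytest.fixture
def water() -> FluidMedium:
    return FluidMedium(rho_f=1000.0, c_f=1543.0, mu_f=WATER_MU)


@pytest.fixture
def blood() -> FluidMedium:
    return FluidMedium(rho_f=1000.0, c_f=1543.0, mu_f=BLOOD_MU)


@pytest.fixture
def drive50() -> AcousticDrive:
    """Reference drive of the estimator performance study: 20 Pa at 50 Hz."""
    return AcousticDrive(P_f=20.0, f0=50.0)


@pytest.fixture
def particle500() -> DonorParticle:
    """500 µm neutrally buoyant donor lump, worst-case single-acceptor pairing."""
    return DonorParticle(d_p=500e-6, R0=10e-9, k_A=1.0)


@pytest.fixture
def protocol_small() -> EstimationProtocol:
    return EstimationProtocol(NT=5, Nm=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
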