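import numpy as np
import pytest

from bayesmech import Precisions, StateVector
from bayesmech.experiments import section51_params

# Exact spontaneous attractor centre of the published parameter set,
# frozen from an independent symbolic (sympy, exact Gaussian-integer)
# solve of R Psi_c = I_sp.
CENTRE_S0 = np.array([-10 - 10j, 10 + 15j, -20 - 10j, 5 - 10j])
CENTRE_S100 = np.array([-10 - 110j, 10 + 65j, -20 - 110j, 55 - 10j])
INTENSITY_S0 = 1150.0
INTENSITY_S100 = 32150.0


@pytest.fixture(scope="session")
def params51():
    return section51_params()


@pytest.fixture(scope="session")
def model51(params51):
    return params51.to_generative_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230414)


def random_state(rng) -> StateVector:
    v = rng.normal(size=4, scale=5.0) + 1j * rng.normal(size=4, scale=5.0)
    return StateVector.from_array(v)


def random_params(rng, real=False):
    from bayesmech.linear import LinearParams

    def draw():
        z = rng.normal(scale=2.0) + (0 if real else 1j * rng.normal(scale=2.0))
        return complex(z)

    masses = rng.uniform(0.2, 5.0, size=3)
    return LinearParams(
        theta_g0=draw(), theta_g1=draw(), theta_g2=draw(),
        theta_f0=draw(), theta_f1=draw(),
        theta_pi0=draw(), theta_pi2=draw(),
        precisions=Precisions(*masses),
    )
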