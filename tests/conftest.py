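import numpy as np
import pytest

from emikin.network import Reaction, Species, build_network
from emikin.params import RateParameters, default_params
from emikin.two_arm import TernaryPathwayConfig, build_two_arm


@pytest.fixture
def params() -> RateParameters:
    return default_params()


@pytest.fixture(scope="session")
def two_arm_net():
    return build_two_arm(TernaryPathwayConfig(solution_phase_activation=True))


@pytest.fixture
def binding_pair():
    """Minimal M + X <-> M:X network (the quadratic-isotherm oracle system)."""
    species = [
        Species("X", "solution", {"FX": 1}),
        Species("M", "solution", {"M": 1}),
        Species("M:X", "solution", {"M": 1, "FX": 1}),
    ]
    reactions = [
        Reaction((("M", 1), ("X", 1)), (("M:X", 1),), "kMX_on", "association"),
        Reaction((("M:X", 1),), (("M", 1), ("X", 1)), "kMX_off", "dissociation"),
    ]
    return build_network(species, reactions, name="binding_pair")


def isotherm_complex(a0: float, b0: float, kd: float) -> float:
    """Closed-form equilibrium complex concentration for A + B <-> AB."""
    b = a0 + b0 + kd
    return (b - np.sqrt(b * b - 4.0 * a0 * b0)) / 2.0
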