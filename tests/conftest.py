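import numpy as np
import pytest

from ctquench.kinetics import build_network
from ctquench.marcus import MarcusParams
from ctquench.synthetic import StructureSpec, generate_dimer_structure

# reference Marcus parameters of the two lutein sites (printed inputs)
L1_PARAMS = MarcusParams(coupling=240.0, reorganization=5405.0, driving_force=-82.0)
L2_PARAMS = MarcusParams(coupling=279.0, reorganization=5052.0, driving_force=951.0)


@pytest.fixture(scope="session")
def default_network():
    """The default five-state quenching network with Marcus rates."""
    from ctquench.marcus import marcus_rate

    return build_network(
        k_cs1=marcus_rate(L1_PARAMS),
        k_cs2=marcus_rate(L2_PARAMS),
        dg1=L1_PARAMS.driving_force,
        dg2=L2_PARAMS.driving_force,
    )


@pytest.fixture(scope="session")
def default_structure():
    return generate_dimer_structure(StructureSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
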