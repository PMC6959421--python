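import numpy as np
import pytest

from chondrosim import (CellFractions, GrowthCoefficients, ModelParameters,
                        build_mesh, derived_parameters)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def dp(params):
    return derived_parameters(params)


@pytest.fixture()
def mesh():
    return build_mesh(0.01, 50)


@pytest.fixture()
def uniform_state(mesh):
    """Spatially uniform fractions and zero growth on the default mesh."""
    n = mesh.N + 1
    fr = CellFractions(*(np.full(n, 0.002) for _ in range(4)))
    g = GrowthCoefficients(*(np.zeros(n) for _ in range(4)))
    return fr, g
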