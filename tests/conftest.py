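import numpy as np
import pytest

from petalfem.corolla_geometry import LaminaSpec, build_lamina


@pytest.fixture(scope="session")
def coarse_spec():
    return LaminaSpec(target_edge_length=1.0)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_spec):
    return build_lamina(coarse_spec)


@pytest.fixture(scope="session")
def default_mesh():
    """The study-resolution lamina (~2000 shell elements)."""
    return build_lamina(LaminaSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
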