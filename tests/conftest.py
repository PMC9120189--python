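import numpy as np
import pytest

from menpsim import network_voxel
from menpsim.particle_magnetics import ParticleSpec, get_material


@pytest.fixture(scope="session")
def cfo():
    return get_material("cobalt_ferrite")


@pytest.fixture(scope="session")
def bto():
    return get_material("barium_titanate")


@pytest.fixture(scope="session")
def menp_spec(cfo, bto):
    """30 nm CFO-BTO particle with a 12 nm core at 300 K."""
    return ParticleSpec(
        r_total=15e-9, r_core=12e-9, core_material=cfo, shell_material=bto
    )


@pytest.fixture(scope="session")
def spion_spec():
    return ParticleSpec(
        r_total=15e-9, r_core=15e-9, core_material=get_material("spion")
    )


@pytest.fixture(scope="session")
def default_network():
    """The full layered column network (built once per session)."""
    return network_voxel.build_network(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
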