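import numpy as np
import pytest

from dendrisorb import (DendrimerSpec, ForceFieldParams, SimulationParams,
                        build_topology, embed_3d, relax)


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def g1_conformation(ff):
    top = build_topology(DendrimerSpec("C4", 1))
    return embed_3d(top, seed=11, forcefield=ff)


@pytest.fixture(scope="session")
def g2_equilibrated(ff):
    """Short thermostatted equilibration of a C4 G2 dendrimer."""
    top = build_topology(DendrimerSpec("C4", 2))
    conf = embed_3d(top, seed=5, forcefield=ff)
    traj = relax(conf, ff, SimulationParams(duration_ps=5.0, seed=5))
    return traj.final_conformation(), traj.velocities[-1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
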