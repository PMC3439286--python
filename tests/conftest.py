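import numpy as np
import pytest
import scipy.sparse as sp

from rdmesim.mesh import generate_interval_mesh
from rdmesim.model import MassActionReaction, RDMEModel, Species


@pytest.fixture(scope="session")
def two_voxel_mesh():
    return generate_interval_mesh(2, 1.0)


@pytest.fixture(scope="session")
def two_voxel_Q():
    """Diffusion generator with volumes (2, 1): q12 = d/v1, q21 = d/v2."""
    return sp.csr_matrix(np.array([[-0.5, 0.5], [1.0, -1.0]]))


def make_birth_death_diffusion(mesh, birth=5.0, death=0.5, n0=(5, 0), t_end=5.0, seed=1):
    """2-voxel birth-death-diffusion model with volumes (2, 1)."""
    species = [Species("X", 1.0)]
    reactions = [
        MassActionReaction("birth", birth, {}, {"X": 1}),
        MassActionReaction("death", death, {"X": 1}, {}),
    ]
    return RDMEModel(
        mesh=mesh,
        species=species,
        reactions=reactions,
        u0=np.array([list(n0)]),
        tspan=np.array([0.0, t_end]),
        volumes=np.array([2.0, 1.0]),
        seed=seed,
    )
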