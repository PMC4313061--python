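import numpy as np
import pytest

from domainflux.model_io import StructureModel, SubdomainPartition, Trajectory
from domainflux.synthetic import TrimerSpec, build_trimer


@pytest.fixture
def tiny_model():
    """Three beads, one chain."""
    return StructureModel(
        atom_index=[1, 2, 3],
        residue_index=[1, 2, 3],
        monomer_id=["A", "A", "A"],
        coords=[[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.6, 1.0, -2.0]],
    )


@pytest.fixture
def three_chain_model():
    """Chains A, B, C with 10 residues each."""
    rng = np.random.default_rng(42)
    coords = rng.normal(scale=10.0, size=(30, 3))
    return StructureModel(
        atom_index=np.arange(1, 31),
        residue_index=np.tile(np.arange(1, 11), 3),
        monomer_id=np.repeat(["A", "B", "C"], 10),
        coords=coords,
    )


@pytest.fixture(scope="session")
def trimer():
    """Default toy trimer (session-scoped: deterministic and read-only)."""
    return build_trimer(TrimerSpec(seed=1))


@pytest.fixture
def random_trajectory(tiny_model):
    rng = np.random.default_rng(0)
    frames = tiny_model.coords[None] + rng.normal(scale=0.5, size=(20, 3, 3))
    return Trajectory(frames, dt=1.0)
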