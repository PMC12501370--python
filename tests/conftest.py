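import numpy as np
import pytest

from cofoldprobe import (
    LigandGraph,
    ToyComplexParams,
    make_toy_complex,
)
from cofoldprobe.ligand_challenges import ATP_SMILES, GLUCOSE_SMILES
from cofoldprobe.synthetic_data import _embed_ligand


@pytest.fixture(scope="session")
def glucose():
    return LigandGraph.from_smiles(GLUCOSE_SMILES)


@pytest.fixture(scope="session")
def glucose_3d():
    return _embed_ligand("glucose_like", seed=11)


@pytest.fixture(scope="session")
def atp():
    return LigandGraph.from_smiles(ATP_SMILES)


@pytest.fixture(scope="session")
def atp_3d():
    return _embed_ligand("atp_like", seed=11)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(ToyComplexParams(seed=17))


@pytest.fixture()
def benzene_ring():
    """Planar 6-ring with ideal geometry: maximal bond-rotation symmetry."""
    graph = LigandGraph.from_smiles("c1ccccc1")
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    xyz = np.stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)], axis=1)
    return graph.with_coords(xyz)
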