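import numpy as np
import pytest

from opsinscreen.consensus import Pose
from opsinscreen.pharmacophore import LigandConformer
from opsinscreen.synthdata import fixture_model


@pytest.fixture
def model():
    return fixture_model()


@pytest.fixture
def benzene_conformer():
    angles = np.arange(6) * np.pi / 3
    coords = np.stack([1.396 * np.cos(angles), 1.396 * np.sin(angles),
                       np.zeros(6)], axis=1)
    bonds = [(i, (i + 1) % 6, 1.5) for i in range(6)]
    return LigandConformer("benzene", ["C"] * 6, coords, bonds)


BENZENE_SYMBOLS = ("C",) * 6
BENZENE_BONDS = tuple((i, (i + 1) % 6, 1.5) for i in range(6))


def benzene_coords(offset=(0.0, 0.0, 0.0)):
    angles = np.arange(6) * np.pi / 3
    coords = np.stack([1.396 * np.cos(angles), 1.396 * np.sin(angles),
                       np.zeros(6)], axis=1)
    return coords + np.asarray(offset)


def benzene_pose(method, coords, ligand_id="BNZ"):
    return Pose(ligand_id, method, coords, BENZENE_SYMBOLS, BENZENE_BONDS)
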