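import numpy as np
import pytest

import habitkit as hk
from habitkit.synthetic_structures import SPACE_GROUP_OPS


@pytest.fixture(scope="session")
def mono_cell():
    """The monoclinic C2/c cell of the isoxazolidinyl-nucleoside study."""
    return hk.CellParameters(19.9960, 16.7246, 19.1703, 90.0, 116.319, 90.0)


@pytest.fixture(scope="session")
def c2c_ops():
    return [hk.SymmetryOperator.from_triplet(t) for t in SPACE_GROUP_OPS["C2/c"]]


@pytest.fixture(scope="session")
def c2c_laue(c2c_ops):
    return hk.laue_rotations(c2c_ops)


#: the published growth-morphology table: form -> (multiplicity, d_hkl, E_att, TFA %)
GM_TABLE = {
    (1, 1, 0): (4, 12.2279, -214.9592, 57.21),
    (0, 0, 2): (2, 8.5915, -208.9238, 27.50),
    (1, 1, -1): (4, 11.7887, -299.1849, 12.71),
    (1, 1, 1): (4, 8.7861, -255.0837, 2.58),
}


@pytest.fixture(scope="session")
def gm_forms(mono_cell, c2c_laue):
    """FaceForms for the four published forms, with printed E_att values."""
    forms, e_att = [], []
    for hkl, (_, _, e, _) in GM_TABLE.items():
        f = hk.face_multiplicity(c2c_laue, hk.MillerIndex(*hkl))
        f.d_hkl = hk.d_spacing(mono_cell, hkl)
        forms.append(f)
        e_att.append(e)
    return forms, e_att


@pytest.fixture(scope="session")
def lj_potential():
    return hk.PotentialParams(coulomb=False, cutoff=12.0)


@pytest.fixture(scope="session")
def mol_crystal():
    return hk.make_molecular_crystal(space_group="C2/c", z_prime=1)
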