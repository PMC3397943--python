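import numpy as np
import pytest

from pocketscan.structure import Structure


TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 11.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00 12.00           C
ATOM      4  O   ALA A   1      13.339   7.615  -5.855  1.00 13.00           O
ATOM      5  CB  ALA A   1      10.520   6.214  -4.118  1.00 14.00           C
END
"""

GDP_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 11.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00 12.00           C
HETATM    4  PB  GDP A 201       0.500   1.500   2.500  1.00 20.00           P
HETATM    5 MG    MG A 202       3.000   3.000   3.000  1.00 21.00          MG
END
"""


@pytest.fixture
def tiny_pdb_text():
    return TINY_PDB


@pytest.fixture
def gdp_pdb_text():
    return GDP_PDB


def ca_structure(coords, res_ids=None, structure_id="synthetic", res_name="ALA"):
    """Cα-only Structure from raw coordinates (test helper)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if res_ids is None:
        res_ids = np.arange(1, n + 1)
    return Structure(
        id=structure_id,
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        res_name=np.array([res_name] * n),
        res_id=np.asarray(res_ids),
        ins_code=np.array([""] * n),
        chain_id=np.array(["A"] * n),
        coord=coords,
        b_factor=np.zeros(n),
        occupancy=np.ones(n),
    )


def generic_structure(coords, elements, res_ids, res_names=None, structure_id="synthetic"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if res_names is None:
        res_names = ["ALA"] * n
    return Structure(
        id=structure_id,
        atom_name=np.array([f"{e}{i + 1}" for i, e in enumerate(elements)]),
        element=np.asarray(elements),
        res_name=np.asarray(res_names),
        res_id=np.asarray(res_ids),
        ins_code=np.array([""] * n),
        chain_id=np.array(["A"] * n),
        coord=coords,
        b_factor=np.zeros(n),
        occupancy=np.ones(n),
    )
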