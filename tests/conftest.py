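import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ifpscore.structure_io import LigandAtom, LigandMolecule


def hexagon(radius: float = 1.39) -> list[np.ndarray]:
    return [
        radius * np.array([np.cos(np.deg2rad(60 * k)),
                           np.sin(np.deg2rad(60 * k)), 0.0])
        for k in range(6)
    ]


@pytest.fixture
def ethanol() -> LigandMolecule:
    return LigandMolecule(
        atoms=[
            LigandAtom("C", [0.0, 0.0, 0.0], n_hydrogens=3),
            LigandAtom("C", [1.52, 0.0, 0.0], n_hydrogens=2),
            LigandAtom("O", [2.1, 1.2, 0.0], n_hydrogens=1),
        ],
        bonds=[(0, 1, 1, False), (1, 2, 1, False)],
        name="ethanol",
    )


@pytest.fixture
def benzene() -> LigandMolecule:
    return LigandMolecule(
        atoms=[LigandAtom("C", p, aromatic=True, n_hydrogens=1)
               for p in hexagon()],
        bonds=[(k, (k + 1) % 6, 1, True) for k in range(6)],
        name="benzene",
    )


@pytest.fixture
def acetate() -> LigandMolecule:
    # charge localized on one oxygen, as files typically encode it
    return LigandMolecule(
        atoms=[
            LigandAtom("C", [0.0, 0.0, 0.0], n_hydrogens=3),
            LigandAtom("C", [1.52, 0.0, 0.0], n_hydrogens=0),
            LigandAtom("O", [2.12, 1.06, 0.0], formal_charge=-1),
            LigandAtom("O", [2.12, -1.06, 0.0]),
        ],
        bonds=[(0, 1, 1, False), (1, 2, 1, False), (1, 3, 2, False)],
        name="acetate",
    )


def sdf_text(smiles: str, name: str) -> str:
    """Programmatic SDF fixture from a SMILES string."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    AllChem.EmbedMolecule(mol, randomSeed=7)
    mol = Chem.RemoveHs(mol)
    mol.SetProp("_Name", name)
    return Chem.MolToMolBlock(mol) + "$$$$\n"


@pytest.fixture
def benzene_sdf(tmp_path) -> Path:
    p = tmp_path / "benzene.sdf"
    p.write_text(sdf_text("c1ccccc1", "benzene"))
    return p


@pytest.fixture
def ethanol_sdf(tmp_path) -> Path:
    p = tmp_path / "ethanol.sdf"
    p.write_text(sdf_text("CCO", "ethanol"))
    return p


ACETATE_MOL2 = """@<TRIPOS>MOLECULE
acetate
 4 3 1 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 C1          0.0000    0.0000    0.0000 C.3     1  ACT         0.0000
      2 C2          1.5200    0.0000    0.0000 C.2     1  ACT         0.0000
      3 O1          2.1200    1.0600    0.0000 O.co2   1  ACT        -1.0000
      4 O2          2.1200   -1.0600    0.0000 O.co2   1  ACT         0.0000
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
     3    2    4 2
@<TRIPOS>SUBSTRUCTURE
     1 ACT         1 GROUP
"""


@pytest.fixture
def acetate_mol2(tmp_path) -> Path:
    p = tmp_path / "acetate.mol2"
    p.write_text(ACETATE_MOL2)
    return p


MINIMAL_PDB = """ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
ATOM      4  O   ALA A   1      13.619   7.308  -5.711  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.270   4.694  -4.915  1.00  0.00           C
ATOM      6  N   GLY A   2      12.544   7.926  -3.842  1.00  0.00           N
ATOM      7  CA  GLY A   2      13.496   8.990  -3.522  1.00  0.00           C
ATOM      8  C   GLY A   2      13.019  10.342  -4.039  1.00  0.00           C
ATOM      9  O   GLY A   2      11.880  10.480  -4.486  1.00  0.00           O
HETATM   10  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""

HETATM_ONLY_PDB = """HETATM    1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  C2  LIG A   1       1.500   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path) -> Path:
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def hetatm_only_pdb(tmp_path) -> Path:
    p = tmp_path / "hetatm.pdb"
    p.write_text(HETATM_ONLY_PDB)
    return p
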