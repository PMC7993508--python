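"""Reading, cleaning and filtering of protein and ligand structures.

Proteins come in as PDB files (parsed with Biopython), ligands as SDF or
MOL2 (parsed with RDKit).  Both are converted into lightweight plain-data
containers (:class:`ProteinStructure`, :class:`LigandMolecule`) that the
rest of the package consumes, so downstream geometry and graph code never
depends on the parser that produced a structure.

Dataset-level curation mirrors the usual refined-set protocol: waters are
stripped, polar hydrogens may be added geometrically, complexes are kept
only when the crystal resolution is strictly better than a cutoff and the
affinity label is a dissociation or inhibition constant (pKd/pKi).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by three-letter code.  This
#: ordering is the canonical residue axis of the interaction fingerprint.
STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Raised when a structure file cannot be parsed or is unusable."""


@dataclass
class Atom:
    """One protein atom: PDB atom name, element, coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: bad coordinates {self.coord}")


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_AA

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinStructure:
    """An ordered collection of residues with preprocessing flags."""

    residues: list[Residue]
    resolution: float | None = None
    waters_removed: bool = False
    hydrogens_present: bool = False

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_standard]


@dataclass
class LigandAtom:
    """One heavy ligand atom with perceived chemistry attached."""

    element: str
    coord: np.ndarray
    aromatic: bool = False
    formal_charge: int = 0
    n_hydrogens: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)


@dataclass
class LigandMolecule:
    """Heavy-atom ligand graph: atoms plus (i, j, order, aromatic) bonds."""

    atoms: list[LigandAtom]
    bonds: list[tuple[int, int, int, bool]]
    name: str = "LIG"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond ({i},{j}) references missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[tuple[int, int, bool]]]:
        """Neighbor lists: adjacency()[i] -> [(j, order, aromatic), ...]."""
        adj: list[list[tuple[int, int, bool]]] = [[] for _ in self.atoms]
        for i, j, order, arom in self.bonds:
            adj[i].append((j, order, arom))
            adj[j].append((i, order, arom))
        return adj

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def is_connected(self) -> bool:
        if not self.atoms:
            return False
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for j, _, _ in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == len(self.atoms)


@dataclass
class ComplexRecord:
    """One protein-ligand complex with its affinity label and metadata."""

    id: str
    protein: ProteinStructure | None = None
    ligand: LigandMolecule | None = None
    affinity: float | None = None
    affinity_type: str | None = None  # "Kd" | "Ki" | "IC50"
    resolution: float | None = None
    protein_path: str | None = None
    ligand_path: str | None = None


# ---------------------------------------------------------------------------
# protein reading
# ---------------------------------------------------------------------------

# Donor heavy atoms that receive a geometrically placed polar hydrogen when
# none is present in the file.  Backbone N is handled for every residue.
_SIDECHAIN_DONOR_ATOMS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"), "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
}


def read_protein(
    path: str | Path,
    add_hydrogens: bool = False,
    remove_waters: bool = True,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Waters (HOH/WAT) are removed when ``remove_waters`` is set.  When
    ``add_hydrogens`` is set and a donor heavy atom has no hydrogen within
    bonding distance, a single polar hydrogen is placed 1.0 A along the
    direction pointing away from the donor's bonded heavy neighbours; this
    is sufficient for donor-H-acceptor angle screening, not a protonation
    model.  Non-standard residues are retained but are ignored by
    featurization.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises a zoo of exceptions
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    residues: list[Residue] = []
    model = next(iter(structure), None)
    if model is None:
        raise StructureError(f"{path}: no model found")
    for chain in model:
        for res in chain:
            resname = res.get_resname().strip()
            if remove_waters and resname in WATER_NAMES:
                continue
            atoms = [
                Atom(
                    name=a.get_name().strip(),
                    element=(a.element or a.get_name().strip()[0]).capitalize(),
                    coord=np.asarray(a.get_coord(), dtype=float),
                )
                for a in res
            ]
            residues.append(
                Residue(chain=chain.id, number=res.id[1], name=resname, atoms=atoms)
            )

    prot = ProteinStructure(
        residues=residues,
        resolution=getattr(structure.header, "get", lambda *_: None)("resolution"),
        waters_removed=remove_waters,
    )
    if isinstance(structure.header, dict):
        prot.resolution = structure.header.get("resolution")
    if not prot.standard_residues():
        raise StructureError(f"{path}: no standard amino-acid residues")
    if add_hydrogens:
        _add_polar_hydrogens(prot)
    prot.hydrogens_present = any(
        a.element == "H" for r in prot.residues for a in r.atoms
    )
    return prot


def _add_polar_hydrogens(prot: ProteinStructure) -> None:
    """Place one H on each bare donor, pointing away from bonded neighbours."""
    for res in prot.residues:
        if not res.is_standard:
            continue
        donors = list(_SIDECHAIN_DONOR_ATOMS.get(res.name, ()))
        if res.name != "PRO":
            donors.append("N")
        coords = np.array([a.coord for a in res.atoms])
        for dname in donors:
            donor = res.atom(dname)
            if donor is None:
                continue
            dist = np.linalg.norm(coords - donor.coord, axis=1)
            near = [
                res.atoms[i]
                for i in np.nonzero((dist > 1e-6) & (dist < 1.8))[0]
            ]
            if any(a.element == "H" for a in near):
                continue
            heavy = [a for a in near if a.element != "H"]
            if not heavy:
                continue
            centroid = np.mean([a.coord for a in heavy], axis=0)
            direction = donor.coord - centroid
            norm = np.linalg.norm(direction)
            if norm < 1e-6:
                continue
            hpos = donor.coord + direction / norm * 1.0
            res.atoms.append(Atom(name=f"H{dname}"[:4], element="H", coord=hpos))


def write_protein_pdb(prot: ProteinStructure, path: str | Path) -> None:
    """Write a minimal, standards-conforming PDB file."""
    lines = []
    serial = 1
    for res in prot.residues:
        record = "ATOM" if res.is_standard or res.is_water else "HETATM"
        for atom in res.atoms:
            name = atom.name
            # columns 13-16: names <4 chars start at col 14
            name_field = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"{record:<6s}{serial:>5d} {name_field}"
                f" {res.name:<3s} {res.chain}{res.number:>4d}    "
                f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element.upper():>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ligand reading
# ---------------------------------------------------------------------------

def ligand_from_rdkit(mol, name: str = "LIG") -> LigandMolecule:
    """Convert an RDKit Mol (with a conformer) to a heavy-atom graph."""
    from rdkit import Chem

    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(
            LigandAtom(
                element=a.GetSymbol(),
                coord=np.array([pos.x, pos.y, pos.z]),
                aromatic=a.GetIsAromatic(),
                formal_charge=a.GetFormalCharge(),
                n_hydrogens=a.GetTotalNumHs(),
            )
        )
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            int(b.GetBondTypeAsDouble()) if not b.GetIsAromatic() else 1,
            b.GetIsAromatic(),
        )
        for b in mol.GetBonds()
    ]
    return LigandMolecule(atoms=atoms, bonds=bonds, name=name)


def read_ligand(path: str | Path) -> LigandMolecule:
    """Read the first molecule from an SDF or MOL2 file.

    Aromaticity is perceived by RDKit from the bond block; formal charges
    are taken from the file.  If the molecule has several disconnected
    fragments the largest (by heavy-atom count) is kept with a warning.
    """
    from rdkit import Chem

    path = Path(path)
    suffix = path.suffix.lower()
    mol = None
    if suffix in (".sdf", ".sd", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        mols = [m for m in supplier if m is not None]
        if len(mols) > 1:
            warnings.warn(f"{path}: multiple molecules, taking the first")
        mol = mols[0] if mols else None
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
    else:
        raise StructureError(f"unsupported ligand format: {path.suffix}")
    if mol is None:
        raise StructureError(f"cannot parse ligand file {path}")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        warnings.warn(f"{path}: disconnected ligand, keeping largest fragment")
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
    return ligand_from_rdkit(mol, name=name or path.stem)


# ---------------------------------------------------------------------------
# dataset filtering and the index file
# ---------------------------------------------------------------------------

def filter_complexes(
    records: list[ComplexRecord],
    max_resolution: float = 2.5,
    affinity_types: set[str] = frozenset({"Kd", "Ki"}),
    allow_missing_resolution: bool = False,
) -> list[ComplexRecord]:
    """Keep complexes resolved strictly below ``max_resolution`` Angstrom
    whose label is one of ``affinity_types`` (input order preserved).

    Structures without a resolution (e.g. NMR) are dropped unless
    ``allow_missing_resolution`` is set.
    """
    kept = []
    for rec in records:
        if rec.affinity_type not in affinity_types:
            continue
        if rec.resolution is None:
            if not allow_missing_resolution:
                continue
        elif not rec.resolution < max_resolution:
            continue
        kept.append(rec)
    return kept


def read_index(path: str | Path) -> list[ComplexRecord]:
    """Read an index CSV: id, protein_path, ligand_path, affinity,
    affinity_type, resolution (resolution may be empty)."""
    records = []
    base = Path(path).parent
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            res = row.get("resolution", "")
            records.append(
                ComplexRecord(
                    id=row["id"],
                    protein_path=str(base / row["protein_path"]),
                    ligand_path=str(base / row["ligand_path"]),
                    affinity=float(row["affinity"]) if row.get("affinity") else None,
                    affinity_type=row.get("affinity_type") or None,
                    resolution=float(res) if res not in ("", None) else None,
                )
            )
    return records


def load_complex(rec: ComplexRecord, add_hydrogens: bool = True) -> ComplexRecord:
    """Load the structures referenced by an index record, in place."""
    if rec.protein is None and rec.protein_path:
        rec.protein = read_protein(rec.protein_path, add_hydrogens=add_hydrogens)
    if rec.ligand is None and rec.ligand_path:
        rec.ligand = read_ligand(rec.ligand_path)
    return rec
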