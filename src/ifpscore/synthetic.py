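"""Synthetic protein-ligand complexes with planted interactions, and
synthetic labeled datasets.

The generator builds geometrically exact toy complexes: for every planted
(residue, interaction class, distance) triple it places a minimal ligand
probe group (an apolar carbon, a carbonyl or hydroxyl oxygen, a charged
atom, or a benzene ring) and an idealized residue template whose
functional group sits exactly at the requested distance with compliant
angles.  Probe groups hang off a chain of anchor carbons spaced 30 A
apart, so plants cannot interact with each other; decoy residues are
parked 25 A away from every ligand atom, beyond all cutoffs.

The returned ground-truth fingerprint is implied by the construction.
One physical consequence is included deliberately: an aromatic stack
placed within the stacking cutoff necessarily brings ring carbons within
the hydrophobic contact cutoff, so aromatic plants also contribute a
hydrophobic contact for the same residue whenever the constructed ring
geometry implies one.

Residue templates use idealized internal coordinates (no rotamer
library); they are sufficient for exercising the geometric rules, not
for physical realism.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import LabeledDataset, feature_names as _feature_names
from .fragments import FragmentDictionary
from .interactions import (
    CLASSES,
    GeometricRules,
    IFPVector,
    N_CELLS,
    PROTEIN_HYDROPHOBIC,
    cell_index,
)
from .structure_io import (
    Atom,
    LigandAtom,
    LigandMolecule,
    ProteinStructure,
    Residue,
    write_protein_pdb,
)

_Z = np.array([0.0, 0.0, 1.0])
_SPACING = 30.0  # A between probe anchors; larger than every cutoff

# ---------------------------------------------------------------------------
# residue templates
#
# Local frame: the contact atom (or ring centroid) is at the origin, the
# ligand probe lies along -z, and the rest of the residue extends to +z.
# Hydrogens are included only where the H-bond donor angle needs them.
# ---------------------------------------------------------------------------

_T = tuple[str, str, tuple[float, float, float]]  # (atom name, element, xyz)


def _backbone(x0: float, z0: float) -> list[_T]:
    return [
        ("CA", "C", (x0, 0.0, z0)),
        ("N", "N", (x0 + 1.2, 0.0, z0 + 0.8)),
        ("C", "C", (x0 - 1.2, 0.0, z0 + 0.8)),
        ("O", "O", (x0 - 2.3, 0.0, z0 + 0.4)),
    ]


def _hexagon(radius: float = 1.39, plane: str = "xy") -> list[tuple[float, float, float]]:
    pts = []
    for k in range(6):
        a = np.deg2rad(60.0 * k)
        if plane == "xy":
            pts.append((radius * np.cos(a), radius * np.sin(a), 0.0))
        else:  # xz
            pts.append((radius * np.cos(a), 0.0, radius * np.sin(a)))
    return pts


def _aromatic_template(resname: str, cls: str) -> list[_T]:
    plane = "xy" if cls == "AR_F2F" else "xz"
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms: list[_T] = [
        (name, "C", xyz) for name, xyz in zip(ring_names, _hexagon(plane=plane))
    ]
    # attach CB above the CG ring atom, backbone further +z
    cg = np.array(atoms[0][2])
    cb = cg + np.array([0.0, 0.0, 1.5])
    atoms.append(("CB", "C", tuple(cb)))
    atoms += _backbone(cb[0], cb[2] + 1.5)
    if resname == "TYR":
        cz = np.array(atoms[3][2])
        out = cz / np.linalg.norm(cz)
        atoms.append(("OH", "O", tuple(cz + 1.4 * out)))
    return atoms


def _templates(resname: str, cls: str) -> list[_T]:
    if cls in ("AR_F2F", "AR_E2F"):
        return _aromatic_template(resname, cls)
    t: dict[tuple[str, str], list[_T]] = {
        ("LEU", "HYDROPHOBIC"): [
            ("CD1", "C", (0, 0, 0)),
            ("CG", "C", (0, 0, 1.54)),
            ("CD2", "C", (1.3, 0, 2.3)),
            ("CB", "C", (-1.2, 0, 2.3)),
        ] + _backbone(-1.2, 3.8),
        ("ALA", "HYDROPHOBIC"): [
            ("CB", "C", (0, 0, 0)),
        ] + _backbone(0.0, 1.54),
        ("VAL", "HYDROPHOBIC"): [
            ("CG1", "C", (0, 0, 0)),
            ("CB", "C", (0, 0, 1.54)),
            ("CG2", "C", (1.3, 0, 2.3)),
        ] + _backbone(-1.2, 2.3),
        ("SER", "HBOND_ACC_LIG"): [
            ("OG", "O", (0, 0, 0)),
            ("HG", "H", (0, 0, -1.0)),
            ("CB", "C", (0, 0, 1.43)),
        ] + _backbone(1.2, 2.2),
        ("THR", "HBOND_ACC_LIG"): [
            ("OG1", "O", (0, 0, 0)),
            ("HG1", "H", (0, 0, -1.0)),
            ("CB", "C", (0, 0, 1.43)),
            ("CG2", "C", (1.3, 0, 2.2)),
        ] + _backbone(-1.2, 2.2),
        ("ARG", "HBOND_ACC_LIG"): [
            # backbone amide donates; the guanidinium is parked far +z
            ("N", "N", (0, 0, 0)),
            ("HN", "H", (0, 0, -1.0)),
            ("CA", "C", (0, 0, 1.46)),
            ("C", "C", (1.2, 0, 2.3)),
            ("O", "O", (2.35, 0, 2.3)),
            ("CB", "C", (-1.2, 0, 2.3)),
            ("CG", "C", (-1.2, 0, 3.8)),
            ("CD", "C", (0, 0, 4.6)),
            ("NE", "N", (0, 1.0, 5.5)),
            ("CZ", "C", (0, 1.0, 6.8)),
            ("NH1", "N", (0, 0.2, 7.6)),
            ("NH2", "N", (0, 2.0, 7.6)),
        ],
        ("ASN", "HBOND_DON_LIG"): [
            ("OD1", "O", (0, 0, 0)),
            ("CG", "C", (0, 0, 1.23)),
            ("ND2", "N", (1.2, 0, 1.9)),
            ("CB", "C", (-1.2, 0, 2.0)),
        ] + _backbone(-1.2, 3.5),
        ("GLN", "HBOND_DON_LIG"): [
            ("OE1", "O", (0, 0, 0)),
            ("CD", "C", (0, 0, 1.23)),
            ("NE2", "N", (1.2, 0, 1.9)),
            ("CG", "C", (-1.2, 0, 2.0)),
            ("CB", "C", (-1.2, 0, 3.5)),
        ] + _backbone(0.0, 4.3),
        ("GLY", "HBOND_DON_LIG"): [
            # backbone carbonyl accepts the ligand's hydrogen
            ("O", "O", (0, 0, 0)),
            ("C", "C", (0, 0, 1.23)),
            ("CA", "C", (1.2, 0, 1.9)),
            ("N", "N", (1.2, 0, 3.4)),
        ],
        ("ARG", "IONIC_LIG_NEG"): [
            ("NH1", "N", (0, 0, 0)),
            ("CZ", "C", (0, 0, 1.33)),
            ("NH2", "N", (1.15, 0, 2.0)),
            ("NE", "N", (-1.15, 0, 2.0)),
            ("CD", "C", (-1.15, 0, 3.5)),
            ("CG", "C", (0, 0, 4.3)),
            ("CB", "C", (0, 0, 5.8)),
        ] + _backbone(1.2, 6.6),
        ("LYS", "IONIC_LIG_NEG"): [
            ("NZ", "N", (0, 0, 0)),
            ("CE", "C", (0, 0, 1.5)),
            ("CD", "C", (0, 0, 3.0)),
            ("CG", "C", (1.2, 0, 3.8)),
            ("CB", "C", (1.2, 0, 5.3)),
        ] + _backbone(0.0, 6.1),
        ("ASP", "IONIC_LIG_POS"): [
            ("OD1", "O", (0, 0, 0)),
            ("CG", "C", (0, 0, 1.25)),
            ("OD2", "O", (1.1, 0, 1.9)),
            ("CB", "C", (-1.2, 0, 2.0)),
        ] + _backbone(-1.2, 3.5),
        ("GLU", "IONIC_LIG_POS"): [
            ("OE1", "O", (0, 0, 0)),
            ("CD", "C", (0, 0, 1.25)),
            ("OE2", "O", (1.1, 0, 1.9)),
            ("CG", "C", (-1.2, 0, 2.0)),
            ("CB", "C", (-1.2, 0, 3.5)),
        ] + _backbone(0.0, 4.3),
    }
    key = (resname, cls)
    if key not in t:
        raise ValueError(f"residue {resname} cannot plant class {cls}")
    return t[key]


#: residues available for planting each interaction class
SUPPORTED_PLANTS: dict[str, tuple[str, ...]] = {
    "HYDROPHOBIC": ("LEU", "ALA", "VAL"),
    "AR_F2F": ("PHE", "TYR"),
    "AR_E2F": ("PHE", "TYR"),
    "HBOND_ACC_LIG": ("SER", "THR", "ARG"),
    "HBOND_DON_LIG": ("ASN", "GLN", "GLY"),
    "IONIC_LIG_NEG": ("ARG", "LYS"),
    "IONIC_LIG_POS": ("ASP", "GLU"),
}

#: distance windows (A) that keep a plant unambiguous for its class
PLANT_DISTANCE_RANGES: dict[str, tuple[float, float]] = {
    "HYDROPHOBIC": (3.3, 4.4),
    "AR_F2F": (3.3, 3.9),
    "AR_E2F": (4.7, 5.4),
    "HBOND_ACC_LIG": (2.6, 3.4),
    "HBOND_DON_LIG": (2.6, 3.4),
    "IONIC_LIG_NEG": (2.7, 3.9),
    "IONIC_LIG_POS": (2.7, 3.9),
}

_CLASS_CUTOFF_ATTR = {
    "HYDROPHOBIC": "hydrophobic_cutoff",
    "AR_F2F": "f2f_centroid_cutoff",
    "AR_E2F": "e2f_centroid_cutoff",
    "HBOND_ACC_LIG": "hbond_da_cutoff",
    "HBOND_DON_LIG": "hbond_da_cutoff",
    "IONIC_LIG_NEG": "ionic_cutoff",
    "IONIC_LIG_POS": "ionic_cutoff",
}


@dataclass
class PlantSpec:
    """What to plant: (residue name, interaction class, distance A) triples
    plus a number of decoy residues placed beyond every cutoff."""

    planted: list[tuple[str, str, float]]
    decoys: int = 0
    seed: int = 0

    def validate(self, rules: GeometricRules) -> None:
        for resname, cls, dist in self.planted:
            if cls not in CLASSES:
                raise ValueError(f"unknown interaction class {cls!r}")
            if resname not in SUPPORTED_PLANTS[cls]:
                raise ValueError(
                    f"residue {resname} cannot support class {cls}; "
                    f"choose from {SUPPORTED_PLANTS[cls]}")
            cutoff = getattr(rules, _CLASS_CUTOFF_ATTR[cls])
            if not 0.0 < dist <= cutoff:
                raise ValueError(
                    f"{resname}/{cls}: distance {dist} outside (0, {cutoff}]")
        if self.decoys < 0:
            raise ValueError("decoys must be >= 0")


def _build_probe(cls: str, anchor: np.ndarray, atoms: list[LigandAtom],
                 bonds: list, anchor_idx: int) -> np.ndarray:
    """Append the ligand probe group for one class; returns the contact
    point (probe atom position, or ring centroid for aromatic classes)."""
    if cls == "HYDROPHOBIC":
        atoms.append(LigandAtom("C", anchor + 1.5 * _Z, n_hydrogens=3))
        bonds.append((anchor_idx, len(atoms) - 1, 1, False))
        return atoms[-1].coord
    if cls == "HBOND_ACC_LIG":  # carbonyl oxygen: acceptor, no H
        atoms.append(LigandAtom("O", anchor + 1.25 * _Z, n_hydrogens=0))
        bonds.append((anchor_idx, len(atoms) - 1, 2, False))
        return atoms[-1].coord
    if cls == "HBOND_DON_LIG":  # hydroxyl oxygen: donor (and acceptor)
        atoms.append(LigandAtom("O", anchor + 1.43 * _Z, n_hydrogens=1))
        bonds.append((anchor_idx, len(atoms) - 1, 1, False))
        return atoms[-1].coord
    if cls == "IONIC_LIG_NEG":
        atoms.append(LigandAtom("O", anchor + 1.3 * _Z, formal_charge=-1))
        bonds.append((anchor_idx, len(atoms) - 1, 1, False))
        return atoms[-1].coord
    if cls == "IONIC_LIG_POS":
        atoms.append(LigandAtom("N", anchor + 1.5 * _Z, formal_charge=1,
                                n_hydrogens=3))
        bonds.append((anchor_idx, len(atoms) - 1, 1, False))
        return atoms[-1].coord
    # aromatic probe: benzene ring parallel to the xy-plane
    center = anchor + 2.9 * _Z
    first = len(atoms)
    for xyz in _hexagon(plane="xy"):
        atoms.append(LigandAtom("C", center + np.array(xyz), aromatic=True,
                                n_hydrogens=1))
    for k in range(6):
        bonds.append((first + k, first + (k + 1) % 6, 1, True))
    bonds.append((anchor_idx, first, 1, False))
    atoms[first].n_hydrogens = 0  # the anchored ring carbon
    return center


def make_toy_complex(
    spec: PlantSpec, rules: GeometricRules | None = None
) -> tuple[ProteinStructure, LigandMolecule, IFPVector]:
    """Build a toy complex realizing a :class:`PlantSpec` exactly.

    Returns the protein, the ligand, and the ground-truth fingerprint the
    construction implies (planted cells, plus the hydrophobic contacts
    that aromatic stacking geometrically entails).
    """
    rules = rules or GeometricRules()
    spec.validate(rules)
    rng = np.random.default_rng(spec.seed)

    lig_atoms: list[LigandAtom] = []
    lig_bonds: list[tuple[int, int, int, bool]] = []
    residues: list[Residue] = []
    anchor_indices: list[int] = []
    probe_slots: list[tuple[str, int, np.ndarray]] = []  # (cls, residue idx, contact)

    n_slots = max(len(spec.planted), 1)
    for k, (resname, cls, dist) in enumerate(spec.planted):
        anchor = np.array([_SPACING * k, 0.0, 0.0])
        lig_atoms.append(LigandAtom("C", anchor, n_hydrogens=0))
        anchor_idx = len(lig_atoms) - 1
        anchor_indices.append(anchor_idx)
        if len(anchor_indices) > 1:
            lig_bonds.append((anchor_indices[-2], anchor_idx, 1, False))
        contact = _build_probe(cls, anchor, lig_atoms, lig_bonds, anchor_idx)

        origin = contact + dist * _Z
        atoms = [
            Atom(name=n, element=e, coord=origin + np.asarray(xyz, float))
            for n, e, xyz in _templates(resname, cls)
        ]
        residues.append(Residue(chain="A", number=k + 1, name=resname, atoms=atoms))
        probe_slots.append((cls, k, contact))

    if not spec.planted:  # decoy-only complex still needs a valid ligand
        lig_atoms.append(LigandAtom("C", np.zeros(3), n_hydrogens=3))
        lig_atoms.append(LigandAtom("C", np.array([1.5, 0.0, 0.0]), n_hydrogens=3))
        lig_bonds.append((0, 1, 1, False))

    for d in range(spec.decoys):
        cls = rng.choice(CLASSES)
        resname = rng.choice(SUPPORTED_PLANTS[cls])
        origin = np.array([_SPACING * (d % n_slots), 10.0 * (d // n_slots), -25.0])
        atoms = [
            Atom(name=n, element=e, coord=origin + np.asarray(xyz, float))
            for n, e, xyz in _templates(resname, cls)
        ]
        residues.append(
            Residue(chain="A", number=len(spec.planted) + d + 1, name=resname,
                    atoms=atoms)
        )

    # anchors bonded to heteroatom probes carry no implicit hydrogens worth
    # modelling; leave explicit H counts as set per probe
    ligand = LigandMolecule(atoms=lig_atoms, bonds=lig_bonds, name="TOY")
    protein = ProteinStructure(residues=residues, resolution=1.5,
                               waters_removed=True)
    protein.hydrogens_present = any(
        a.element == "H" for r in residues for a in r.atoms)

    expected = _expected_ifp(spec, residues, ligand, rules)
    return protein, ligand, expected


def _ligand_hydrophobic_coords(mol: LigandMolecule) -> np.ndarray:
    adj = mol.adjacency()
    coords = [
        a.coord
        for i, a in enumerate(mol.atoms)
        if a.element == "C" and a.formal_charge == 0
        and all(mol.atoms[j].element == "C" for j, _, _ in adj[i])
    ]
    return np.array(coords) if coords else np.zeros((0, 3))


def _expected_ifp(
    spec: PlantSpec,
    residues: list[Residue],
    ligand: LigandMolecule,
    rules: GeometricRules,
) -> IFPVector:
    """Ground-truth fingerprint implied by the construction."""
    lig_hydro = _ligand_hydrophobic_coords(ligand)
    per_residue: dict[int, set[str]] = defaultdict(set)
    for k, (resname, cls, _) in enumerate(spec.planted):
        per_residue[k].add(cls)
        hydro_names = PROTEIN_HYDROPHOBIC.get(resname, ())
        coords = np.array(
            [a.coord for a in residues[k].atoms if a.name in hydro_names]
        )
        if len(coords) and len(lig_hydro):
            d = np.linalg.norm(coords[:, None] - lig_hydro[None], axis=-1)
            if d.min() <= rules.hydrophobic_cutoff:
                per_residue[k].add("HYDROPHOBIC")

    values = np.zeros(N_CELLS, dtype=int)
    for k, classes in per_residue.items():
        for cls in classes:
            values[cell_index(spec.planted[k][0], cls)] += 1
    return IFPVector(values)


def random_plant_spec(seed: int, max_plants: int = 4, max_decoys: int = 4
                      ) -> PlantSpec:
    """Draw a random valid PlantSpec (for property tests and audits)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, max_plants + 1))
    planted = []
    for _ in range(n):
        cls = str(rng.choice(CLASSES))
        resname = str(rng.choice(SUPPORTED_PLANTS[cls]))
        lo, hi = PLANT_DISTANCE_RANGES[cls]
        planted.append((resname, cls, float(rng.uniform(lo, hi))))
    return PlantSpec(planted=planted, decoys=int(rng.integers(0, max_decoys + 1)),
                     seed=seed)


# ---------------------------------------------------------------------------
# file export (exercises the real readers)
# ---------------------------------------------------------------------------

def ligand_to_rdkit(mol: LigandMolecule):
    """Build an RDKit Mol (with conformer) from a heavy-atom graph."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in mol.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.formal_charge)
        atom.SetNumExplicitHs(a.n_hydrogens)
        atom.SetNoImplicit(True)
        atom.SetIsAromatic(a.aromatic)
        rw.AddAtom(atom)
    for i, j, order, arom in mol.bonds:
        btype = (Chem.BondType.AROMATIC if arom
                 else {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                       3: Chem.BondType.TRIPLE}[order])
        rw.AddBond(i, j, btype)
        if arom:
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    conf = Chem.Conformer(m.GetNumAtoms())
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.coord)))
    m.AddConformer(conf)
    m.SetProp("_Name", mol.name)
    return m


def write_toy_complex(spec: PlantSpec, outdir: str | Path,
                      rules: GeometricRules | None = None) -> dict[str, Path]:
    """Materialize a toy complex as PDB + SDF + expected-fingerprint CSV."""
    from rdkit import Chem

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protein, ligand, expected = make_toy_complex(spec, rules)

    pdb_path = outdir / "protein.pdb"
    write_protein_pdb(protein, pdb_path)
    sdf_path = outdir / "ligand.sdf"
    writer = Chem.SDWriter(str(sdf_path))
    writer.write(ligand_to_rdkit(ligand))
    writer.close()
    ifp_path = outdir / "expected_ifp.csv"
    names = IFPVector.feature_names
    ifp_path.write_text(
        ",".join(names) + "\n" + ",".join(map(str, expected.values)) + "\n")
    return {"protein": pdb_path, "ligand": sdf_path, "expected_ifp": ifp_path}


# ---------------------------------------------------------------------------
# synthetic labeled datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDatasetSpec:
    """Linear-model dataset: Poisson fingerprint counts (plus distance
    features when requested), labels = weights . features + N(0, sigma^2).

    Defaults model a mid-sized curated training set: 500 complexes, 12
    informative fingerprint cells, unit-scale weights, sigma = 0.1 pK
    units of label noise.
    """

    n: int = 500
    weights: np.ndarray | None = None
    noise_sigma: float = 0.1
    seed: int = 0
    feature_set: str = "ifp"
    n_active_cells: int = 12
    count_rate: float = 1.2

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def make_synthetic_dataset(spec: SyntheticDatasetSpec) -> LabeledDataset:
    """Generate a reproducible labeled dataset from a linear ground truth."""
    from .features import canonical_set_name

    set_name = canonical_set_name(spec.feature_set)
    if set_name not in ("ifp", "ifp+dist"):
        raise ValueError("synthetic datasets cover the fingerprint feature "
                         "sets ('ifp', 'ifp+dist')")
    rng = np.random.default_rng(spec.seed)
    dim = N_CELLS * (2 if set_name == "ifp+dist" else 1)

    if spec.weights is None:
        informative = rng.choice(N_CELLS, size=min(spec.n_active_cells, N_CELLS),
                                 replace=False)
        w = np.zeros(dim)
        w[informative] = rng.normal(0.0, 1.0, size=len(informative))
    else:
        w = np.asarray(spec.weights, dtype=float)
        if w.shape != (dim,):
            raise ValueError(f"weights must have length {dim}")
        informative = np.flatnonzero(w[:N_CELLS] != 0)

    # informative cells carry signal; distractor cells carry counts with
    # zero weight, so the learner has something to ignore
    others = np.setdiff1d(np.arange(N_CELLS), informative)
    distractors = rng.choice(others, size=min(spec.n_active_cells, len(others)),
                             replace=False)
    active = np.concatenate([informative, distractors]).astype(int)
    counts = np.zeros((spec.n, N_CELLS))
    counts[:, active] = rng.poisson(spec.count_rate, size=(spec.n, len(active)))

    if set_name == "ifp+dist":
        dist = np.where(counts > 0, rng.uniform(2.5, 4.5, size=counts.shape), 0.0)
        X = np.hstack([counts, dist])
    else:
        X = counts

    y = X @ w + rng.normal(0.0, spec.noise_sigma, size=spec.n)
    return LabeledDataset(
        ids=[f"syn{i:05d}" for i in range(spec.n)],
        X=X,
        y=y,
        feature_set=set_name,
        feature_names=_feature_names(set_name),
    )
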