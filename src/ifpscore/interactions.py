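"""Geometric detection of protein-ligand interactions and the 140-cell
interaction fingerprint.

Seven interaction classes are detected from atom-typed structures:
hydrophobic contact, aromatic face-to-face, aromatic edge-to-face, H-bond
accepted by the ligand, H-bond donated by the ligand, ionic contact with a
negatively charged ligand atom, and ionic contact with a positively charged
ligand atom.  Each class fires at most once per protein residue; the
fingerprint cell for (amino acid, class) counts how many residues of that
amino acid engage the ligand in that class, so two arginines each H-bonded
to the ligand give the ARG H-bond cell the value 2.

The companion interaction-distance vector stores, for every occupied cell,
the smallest qualifying contact distance (atom-atom, or centroid-centroid
for the aromatic classes) in Angstrom.

Typing conventions (documented in docs/methods.md): formally charged
groups are typed as ions only, so a salt bridge registers as an ionic
contact rather than ionic plus H-bond; histidine counts as a cation only
when both ring protons are present.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np

from .structure_io import (
    STANDARD_AA,
    LigandMolecule,
    ProteinStructure,
    Residue,
)

logger = logging.getLogger(__name__)

#: Interaction classes in canonical order (the fingerprint's second axis).
CLASSES: tuple[str, ...] = (
    "HYDROPHOBIC",
    "AR_F2F",
    "AR_E2F",
    "HBOND_ACC_LIG",
    "HBOND_DON_LIG",
    "IONIC_LIG_NEG",
    "IONIC_LIG_POS",
)

N_CELLS = len(STANDARD_AA) * len(CLASSES)  # 20 * 7 = 140

#: Flattened (amino acid x class) feature names, row-major by amino acid.
IFP_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{aa}_{cls}" for aa in STANDARD_AA for cls in CLASSES
)
INTDIST_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{name}_dist" for name in IFP_FEATURE_NAMES
)

_CELL_INDEX = {
    (aa, cls): i * len(CLASSES) + j
    for i, aa in enumerate(STANDARD_AA)
    for j, cls in enumerate(CLASSES)
}


def cell_index(residue_name: str, interaction_class: str) -> int:
    return _CELL_INDEX[(residue_name, interaction_class)]


@dataclass(frozen=True)
class GeometricRules:
    """Distance/angle thresholds for the seven interaction classes (A, deg).

    The defaults are community-standard fingerprint thresholds; every value
    is configurable and recorded alongside any fingerprint produced.
    """

    hydrophobic_cutoff: float = 4.5
    f2f_centroid_cutoff: float = 4.0
    f2f_plane_angle_max: float = 30.0
    e2f_centroid_cutoff: float = 5.5
    e2f_plane_angle_min: float = 60.0
    e2f_plane_angle_max: float = 90.0
    hbond_da_cutoff: float = 3.5
    hbond_dha_angle_min: float = 120.0
    ionic_cutoff: float = 4.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeometricRules":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class InteractionRecord:
    """One detected contact: which residue, which class, how close."""

    residue_name: str
    residue_id: tuple[str, int]  # (chain, number)
    interaction_class: str
    distance: float


# ---------------------------------------------------------------------------
# pharmacophoric typing
# ---------------------------------------------------------------------------

PROTEIN_CATIONS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
PROTEIN_ANIONS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
PROTEIN_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    ),
}
# Neutral H-bond donors (side chains; backbone N added for every residue
# except proline).  Charged groups are deliberately absent.
PROTEIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "TRP": ("NE1",), "HIS": ("ND1", "NE2"),
}
# Neutral acceptors (backbone carbonyl O added for every residue).
PROTEIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",), "HIS": ("ND1", "NE2"), "MET": ("SD",),
}
# Apolar side-chain atoms: carbons with no N/O neighbour, plus thioether S.
PROTEIN_HYDROPHOBIC: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "CYS": ("CB",),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "HIS": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "THR": ("CG2",),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "VAL": ("CB", "CG1", "CG2"),
}


@dataclass
class TypedAtoms:
    """Pharmacophoric typing of one residue or of the whole ligand.

    Every field is a coordinate array (k x 3); ``rings`` is a list of
    (centroid, unit normal, ring coordinates) triples.  ``donor_hydrogens``
    maps donor row -> coordinates of its explicit hydrogens (empty when
    the structure is heavy-atom only, in which case H-bond screening falls
    back to the distance criterion alone).
    """

    hydrophobic: np.ndarray
    donors: np.ndarray
    acceptors: np.ndarray
    cations: np.ndarray
    anions: np.ndarray
    rings: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    donor_hydrogens: list[np.ndarray] = field(default_factory=list)


def _empty() -> np.ndarray:
    return np.zeros((0, 3))


def _stack(coords: list[np.ndarray]) -> np.ndarray:
    return np.array(coords, dtype=float) if coords else _empty()


def _ring_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # best-fit plane normal = smallest singular vector
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2] / np.linalg.norm(vt[2])
    return centroid, normal, coords


def _his_is_protonated(res: Residue) -> bool:
    names = {a.name for a in res.atoms}
    return {"HD1", "HE2"} <= names or {"HND1", "HNE2"} <= names


def type_protein_residue(res: Residue) -> TypedAtoms | None:
    """Type the atoms of one standard residue; returns None otherwise."""
    if not res.is_standard:
        logger.debug("skipping non-standard residue %s", res.name)
        return None

    def pick(names: tuple[str, ...]) -> list[np.ndarray]:
        return [a.coord for a in res.atoms if a.name in names]

    hydrophobic = pick(PROTEIN_HYDROPHOBIC.get(res.name, ()))
    donors = pick(PROTEIN_DONORS.get(res.name, ()))
    if res.name != "PRO":
        donors += pick(("N",))
    acceptors = pick(PROTEIN_ACCEPTORS.get(res.name, ())) + pick(("O",))
    cations = pick(PROTEIN_CATIONS.get(res.name, ()))
    if res.name == "HIS" and _his_is_protonated(res):
        cations += pick(("ND1", "NE2"))
    anions = pick(PROTEIN_ANIONS.get(res.name, ())) + pick(("OXT",))

    rings = []
    for ring_names in PROTEIN_RINGS.get(res.name, ()):
        coords = pick(ring_names)
        if len(coords) == len(ring_names):
            rings.append(_ring_frame(np.array(coords)))

    hcoords = np.array(
        [a.coord for a in res.atoms if a.element == "H"], dtype=float
    ).reshape(-1, 3)
    donor_h = []
    for d in donors:
        if len(hcoords):
            near = hcoords[np.linalg.norm(hcoords - d, axis=1) < 1.3]
        else:
            near = _empty()
        donor_h.append(near)

    return TypedAtoms(
        hydrophobic=_stack(hydrophobic),
        donors=_stack(donors),
        acceptors=_stack(acceptors),
        cations=_stack(cations),
        anions=_stack(anions),
        rings=rings,
        donor_hydrogens=donor_h,
    )


def type_ligand(mol: LigandMolecule) -> TypedAtoms:
    """Type ligand atoms from element, charge, aromaticity and neighbours."""
    import networkx as nx

    adj = mol.adjacency()
    anion_idx = {i for i, a in enumerate(mol.atoms) if a.formal_charge < 0}
    # carboxylate symmetry: the sibling oxygen of a charged O shares the
    # negative charge even if the file localizes it on one atom
    for i in list(anion_idx):
        if mol.atoms[i].element != "O":
            continue
        for c, _, _ in adj[i]:
            if mol.atoms[c].element != "C":
                continue
            for o2, _, _ in adj[c]:
                if o2 != i and mol.atoms[o2].element == "O" and len(adj[o2]) == 1:
                    anion_idx.add(o2)

    hydrophobic, donors, acceptors, cations, anions = [], [], [], [], []
    for i, a in enumerate(mol.atoms):
        neighbors = [mol.atoms[j].element for j, _, _ in adj[i]]
        if a.formal_charge > 0:
            cations.append(a.coord)
            continue
        if i in anion_idx:
            anions.append(a.coord)
            continue
        if a.element == "C" and all(el == "C" for el in neighbors):
            hydrophobic.append(a.coord)
        if a.element == "S" and all(el == "C" for el in neighbors):
            hydrophobic.append(a.coord)
        if a.element in ("Cl", "Br", "I"):
            hydrophobic.append(a.coord)
        if a.element in ("N", "O") and a.n_hydrogens >= 1:
            donors.append(a.coord)
        if a.element == "O":
            acceptors.append(a.coord)
        elif a.element == "N" and a.n_hydrogens == 0:
            acceptors.append(a.coord)

    # aromatic rings: cycles in the aromatic-bond subgraph
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((i, j) for i, j, _, arom in mol.bonds if arom)
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) >= 5 and all(mol.atoms[i].aromatic for i in cycle):
            rings.append(_ring_frame(np.array([mol.atoms[i].coord for i in cycle])))

    return TypedAtoms(
        hydrophobic=_stack(hydrophobic),
        donors=_stack(donors),
        acceptors=_stack(acceptors),
        cations=_stack(cations),
        anions=_stack(anions),
        rings=rings,
        donor_hydrogens=[_empty() for _ in donors],
    )


def assign_atom_types(structure) -> TypedAtoms | list[TypedAtoms | None]:
    """Type a ligand, or every residue of a protein (None where untypable)."""
    if isinstance(structure, LigandMolecule):
        return type_ligand(structure)
    if isinstance(structure, ProteinStructure):
        return [type_protein_residue(r) for r in structure.residues]
    raise TypeError(f"cannot type {type(structure).__name__}")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _min_dist(a: np.ndarray, b: np.ndarray) -> float | None:
    """Smallest pairwise distance between two coordinate sets, or None."""
    if len(a) == 0 or len(b) == 0:
        return None
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def _hbond_distance(
    donors: np.ndarray,
    donor_hs: list[np.ndarray],
    acceptors: np.ndarray,
    rules: GeometricRules,
) -> float | None:
    """Closest donor-acceptor distance satisfying the H-bond criteria.

    The D-H...A angle is enforced only for donors with explicit hydrogens;
    heavy-atom-only donors are screened on distance alone.
    """
    best = None
    for d, hs in zip(donors, donor_hs):
        dist = np.linalg.norm(acceptors - d, axis=1)
        for j in np.nonzero(dist <= rules.hbond_da_cutoff)[0]:
            if len(hs):
                dh = d - hs
                ah = acceptors[j] - hs
                cosang = np.einsum("ij,ij->i", dh, ah) / (
                    np.linalg.norm(dh, axis=1) * np.linalg.norm(ah, axis=1)
                )
                angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angles.max() < rules.hbond_dha_angle_min:
                    continue
            if best is None or dist[j] < best:
                best = float(dist[j])
    return best


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring planes, folded into [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def detect_interactions(
    protein: ProteinStructure,
    ligand: LigandMolecule,
    rules: GeometricRules | None = None,
) -> list[InteractionRecord]:
    """Detect all protein-ligand interactions under the geometric rules.

    Returns one record per (residue instance, interaction class), carrying
    the smallest qualifying contact distance.  Records are ordered by
    residue order in the structure, then by canonical class order.
    """
    rules = rules or GeometricRules()
    lig = type_ligand(ligand)
    records: list[InteractionRecord] = []

    for res in protein.residues:
        typed = type_protein_residue(res)
        if typed is None:
            continue
        found: dict[str, float] = {}

        d = _min_dist(typed.hydrophobic, lig.hydrophobic)
        if d is not None and d <= rules.hydrophobic_cutoff:
            found["HYDROPHOBIC"] = d

        # aromatic ring stacking, centroid-centroid distance + plane angle
        f2f = e2f = None
        for pc, pn, _ in typed.rings:
            for lc, ln, _ in lig.rings:
                dist = float(np.linalg.norm(pc - lc))
                angle = _plane_angle(pn, ln)
                if (
                    dist <= rules.f2f_centroid_cutoff
                    and angle <= rules.f2f_plane_angle_max
                ):
                    f2f = dist if f2f is None else min(f2f, dist)
                if (
                    dist <= rules.e2f_centroid_cutoff
                    and rules.e2f_plane_angle_min <= angle <= rules.e2f_plane_angle_max
                ):
                    e2f = dist if e2f is None else min(e2f, dist)
        if f2f is not None:
            found["AR_F2F"] = f2f
        if e2f is not None:
            found["AR_E2F"] = e2f

        d = _hbond_distance(typed.donors, typed.donor_hydrogens, lig.acceptors, rules)
        if d is not None:
            found["HBOND_ACC_LIG"] = d
        d = _hbond_distance(lig.donors, lig.donor_hydrogens, typed.acceptors, rules)
        if d is not None:
            found["HBOND_DON_LIG"] = d

        d = _min_dist(typed.cations, lig.anions)
        if d is not None and d <= rules.ionic_cutoff:
            found["IONIC_LIG_NEG"] = d
        d = _min_dist(typed.anions, lig.cations)
        if d is not None and d <= rules.ionic_cutoff:
            found["IONIC_LIG_POS"] = d

        for cls in CLASSES:
            if cls in found:
                records.append(
                    InteractionRecord(
                        residue_name=res.name,
                        residue_id=(res.chain, res.number),
                        interaction_class=cls,
                        distance=found[cls],
                    )
                )
    return records


# ---------------------------------------------------------------------------
# fingerprint folding
# ---------------------------------------------------------------------------

@dataclass
class IFPVector:
    """140 interaction counts in (amino acid x class) row-major order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (N_CELLS,):
            raise ValueError(f"IFP must have {N_CELLS} cells")

    feature_names = IFP_FEATURE_NAMES


@dataclass
class IntDistVector:
    """140 characteristic contact distances (A); 0 where no interaction."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CELLS,):
            raise ValueError(f"Int-Dist must have {N_CELLS} cells")

    feature_names = INTDIST_FEATURE_NAMES


def build_ifp(records: list[InteractionRecord]) -> IFPVector:
    """Fold interaction records into the 140-length count vector."""
    values = np.zeros(N_CELLS, dtype=int)
    for rec in records:
        if rec.residue_name not in STANDARD_AA:
            logger.warning("skipping non-standard residue %s", rec.residue_name)
            continue
        values[cell_index(rec.residue_name, rec.interaction_class)] += 1
    return IFPVector(values)


def build_intdist(records: list[InteractionRecord]) -> IntDistVector:
    """Fold records into the 140-length minimum-distance vector."""
    values = np.zeros(N_CELLS, dtype=float)
    for rec in records:
        if rec.residue_name not in STANDARD_AA:
            logger.warning("skipping non-standard residue %s", rec.residue_name)
            continue
        i = cell_index(rec.residue_name, rec.interaction_class)
        values[i] = rec.distance if values[i] == 0.0 else min(values[i], rec.distance)
    return IntDistVector(values)


def records_to_tsv(records: list[InteractionRecord]) -> str:
    """Per-complex interaction report (the interpretability surface)."""
    lines = ["chain\tresidue\tresidue_name\tinteraction\tdistance_A"]
    for r in records:
        lines.append(
            f"{r.residue_id[0]}\t{r.residue_id[1]}\t{r.residue_name}"
            f"\t{r.interaction_class}\t{r.distance:.3f}"
        )
    return "\n".join(lines) + "\n"
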