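"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation's code paths: interaction
detection is a plain all-pairs double loop with cross-product ring
normals (no vectorization, no SVD), and sequence-fragment counting walks
every simple path with networkx.  They share only the static typing
tables, which are data, not algorithm.
"""

from __future__ import annotations

import math
from collections import Counter

import networkx as nx

from ifpscore.interactions import (
    CLASSES,
    GeometricRules,
    PROTEIN_ACCEPTORS,
    PROTEIN_ANIONS,
    PROTEIN_CATIONS,
    PROTEIN_DONORS,
    PROTEIN_HYDROPHOBIC,
    PROTEIN_RINGS,
)
from ifpscore.structure_io import LigandMolecule, ProteinStructure


def _dist(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _centroid(coords):
    n = len(coords)
    return [sum(c[k] for c in coords) / n for k in range(3)]


def _normal(coords):
    p0, p1, p2 = coords[0], coords[1], coords[2]
    u = [p1[k] - p0[k] for k in range(3)]
    v = [p2[k] - p0[k] for k in range(3)]
    n = [u[1] * v[2] - u[2] * v[1], u[2] * v[0] - u[0] * v[2],
         u[0] * v[1] - u[1] * v[0]]
    norm = math.sqrt(sum(x * x for x in n))
    return [x / norm for x in n]


def _plane_angle(n1, n2) -> float:
    c = abs(sum(a * b for a, b in zip(n1, n2)))
    return math.degrees(math.acos(min(1.0, max(0.0, c))))


def _angle_at(h, d, a) -> float:
    """D-H...A angle at the hydrogen, degrees."""
    u = [d[k] - h[k] for k in range(3)]
    v = [a[k] - h[k] for k in range(3)]
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    c = sum(x * y for x, y in zip(u, v)) / (nu * nv)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def _ligand_typing(mol: LigandMolecule):
    adj = [[] for _ in mol.atoms]
    for i, j, order, arom in mol.bonds:
        adj[i].append((j, order, arom))
        adj[j].append((i, order, arom))

    anion_idx = {i for i, a in enumerate(mol.atoms) if a.formal_charge < 0}
    for i in list(anion_idx):
        if mol.atoms[i].element != "O":
            continue
        for c, _, _ in adj[i]:
            if mol.atoms[c].element != "C":
                continue
            for o2, _, _ in adj[c]:
                if o2 != i and mol.atoms[o2].element == "O" and len(adj[o2]) == 1:
                    anion_idx.add(o2)

    hydro, donors, acceptors, cations, anions = [], [], [], [], []
    for i, a in enumerate(mol.atoms):
        nb = [mol.atoms[j].element for j, _, _ in adj[i]]
        if a.formal_charge > 0:
            cations.append(list(a.coord))
            continue
        if i in anion_idx:
            anions.append(list(a.coord))
            continue
        if a.element in ("C", "S") and all(e == "C" for e in nb):
            hydro.append(list(a.coord))
        if a.element in ("Cl", "Br", "I"):
            hydro.append(list(a.coord))
        if a.element in ("N", "O") and a.n_hydrogens >= 1:
            donors.append(list(a.coord))
        if a.element == "O" or (a.element == "N" and a.n_hydrogens == 0):
            acceptors.append(list(a.coord))

    rings = []
    g = nx.Graph()
    g.add_edges_from((i, j) for i, j, _, arom in mol.bonds if arom)
    seen = set()
    for cyc in nx.minimum_cycle_basis(g) if g.number_of_edges() else []:
        key = frozenset(cyc)
        if len(cyc) >= 5 and key not in seen and all(
                mol.atoms[i].aromatic for i in cyc):
            seen.add(key)
            coords = [list(mol.atoms[i].coord) for i in cyc]
            rings.append((_centroid(coords), _normal(coords)))
    return hydro, donors, acceptors, cations, anions, rings


def brute_force_interactions(
    protein: ProteinStructure,
    ligand: LigandMolecule,
    rules: GeometricRules | None = None,
) -> set[tuple]:
    """All-pairs reference detector.

    Returns a set of (chain, residue number, residue name, class,
    distance rounded to 1e-6) tuples.
    """
    rules = rules or GeometricRules()
    lh, ld, la, lc, lan, lrings = _ligand_typing(ligand)

    out = set()
    for res in protein.residues:
        if res.name not in PROTEIN_HYDROPHOBIC and res.name not in (
                "GLY", "SER", "ARG", "LYS", "ASP", "GLU", "ASN", "GLN", "HIS",
                "TRP", "TYR", "PHE", "THR", "CYS", "MET", "ILE", "LEU", "VAL",
                "ALA", "PRO"):
            continue

        def named(names):
            return [list(a.coord) for a in res.atoms if a.name in names]

        hydro = named(PROTEIN_HYDROPHOBIC.get(res.name, ()))
        donors = named(PROTEIN_DONORS.get(res.name, ()))
        if res.name != "PRO":
            donors += named(("N",))
        acceptors = named(PROTEIN_ACCEPTORS.get(res.name, ())) + named(("O",))
        cations = named(PROTEIN_CATIONS.get(res.name, ()))
        if res.name == "HIS":
            hnames = {a.name for a in res.atoms}
            if {"HD1", "HE2"} <= hnames or {"HND1", "HNE2"} <= hnames:
                cations += named(("ND1", "NE2"))
        anions = named(PROTEIN_ANIONS.get(res.name, ())) + named(("OXT",))
        hs = [list(a.coord) for a in res.atoms if a.element == "H"]

        best: dict[str, float] = {}

        def keep(cls, d):
            if cls not in best or d < best[cls]:
                best[cls] = d

        for p in hydro:
            for q in lh:
                d = _dist(p, q)
                if d <= rules.hydrophobic_cutoff:
                    keep("HYDROPHOBIC", d)

        for ring_names in PROTEIN_RINGS.get(res.name, ()):
            coords = named(ring_names)
            if len(coords) != len(ring_names):
                continue
            pc, pn = _centroid(coords), _normal(coords)
            for lcen, lnorm in lrings:
                d = _dist(pc, lcen)
                ang = _plane_angle(pn, lnorm)
                if d <= rules.f2f_centroid_cutoff and ang <= rules.f2f_plane_angle_max:
                    keep("AR_F2F", d)
                if (d <= rules.e2f_centroid_cutoff
                        and rules.e2f_plane_angle_min <= ang
                        <= rules.e2f_plane_angle_max):
                    keep("AR_E2F", d)

        for dcoord in donors:
            dhs = [h for h in hs if _dist(h, dcoord) < 1.3]
            for acoord in la:
                d = _dist(dcoord, acoord)
                if d > rules.hbond_da_cutoff:
                    continue
                if dhs and max(_angle_at(h, dcoord, acoord) for h in dhs) \
                        < rules.hbond_dha_angle_min:
                    continue
                keep("HBOND_ACC_LIG", d)

        for dcoord in ld:  # ligand hydrogens are implicit: distance-only
            for acoord in acceptors:
                d = _dist(dcoord, acoord)
                if d <= rules.hbond_da_cutoff:
                    keep("HBOND_DON_LIG", d)

        for p in cations:
            for q in lan:
                d = _dist(p, q)
                if d <= rules.ionic_cutoff:
                    keep("IONIC_LIG_NEG", d)
        for p in anions:
            for q in lc:
                d = _dist(p, q)
                if d <= rules.ionic_cutoff:
                    keep("IONIC_LIG_POS", d)

        for cls in CLASSES:
            if cls in best:
                out.add((res.chain, res.number, res.name, cls,
                         round(best[cls], 6)))
    return out


def records_to_set(records) -> set[tuple]:
    return {
        (r.residue_id[0], r.residue_id[1], r.residue_name,
         r.interaction_class, round(r.distance, 6))
        for r in records
    }


# ---------------------------------------------------------------------------
# fragment oracle
# ---------------------------------------------------------------------------

_BOND = {1: "-", 2: "=", 3: "#"}


def nx_sequence_counts(mol: LigandMolecule, min_atoms: int = 2,
                       max_atoms: int = 6) -> dict[str, int]:
    """Count simple-path fragments by walking every path with networkx."""
    g = nx.Graph()
    for i, a in enumerate(mol.atoms):
        g.add_node(i, sym=a.element.lower() if a.aromatic else a.element)
    for i, j, order, arom in mol.bonds:
        g.add_edge(i, j, sym=":" if arom else _BOND.get(order, "-"))

    counts: Counter[str] = Counter()
    nodes = sorted(g.nodes)
    for ii, i in enumerate(nodes):
        for j in nodes[ii:]:
            if i == j:
                continue
            for path in nx.all_simple_paths(g, i, j, cutoff=max_atoms - 1):
                if len(path) < min_atoms:
                    continue
                sym = [g.nodes[path[0]]["sym"]]
                for a, b in zip(path, path[1:]):
                    sym += [g.edges[a, b]["sym"], g.nodes[b]["sym"]]
                fwd = "".join(sym)
                rev = "".join(sym[::-1])
                counts[min(fwd, rev)] += 1
    return dict(counts)


def random_molecule_graph(rng, max_atoms: int = 30) -> LigandMolecule:
    """Random connected heavy-atom graph: a spanning tree plus extra edges."""
    import numpy as np

    from ifpscore.structure_io import LigandAtom

    n = int(rng.integers(2, max_atoms + 1))
    elements = rng.choice(["C", "N", "O", "S"], size=n, p=[0.6, 0.2, 0.15, 0.05])
    atoms = [
        LigandAtom(str(e), np.asarray(rng.normal(size=3), dtype=float))
        for e in elements
    ]
    bonds = []
    present = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        bonds.append((j, i, int(rng.choice([1, 1, 1, 2])), False))
        present.add((j, i))
    for _ in range(int(rng.integers(0, max(1, n // 4) + 1))):
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        if (i, j) not in present:
            present.add((i, j))
            bonds.append((i, j, 1, False))
    return LigandMolecule(atoms=atoms, bonds=bonds, name="random")
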