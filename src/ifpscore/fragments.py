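"""Substructural molecular fragment descriptors of ligands.

Two fragment families over the heavy-atom graph:

* **sequences** — simple paths of 2 to 6 atoms, rendered as element
  symbols joined by bond symbols (``-`` single, ``=`` double, ``#``
  triple, ``:`` aromatic), aromatic atoms lower-case.  A path and its
  reverse are the same fragment; the canonical label is the
  lexicographic minimum of the two renderings.
* **augmented atoms** — one fragment per heavy atom: the centre symbol
  followed by the sorted multiset of ``(bond symbol + neighbour
  symbol)`` terms, e.g. ``C(-C)(-O)`` for the central carbon of ethanol.

A fragment dictionary built over a training set maps canonical labels to
column indices (lexicographic, gap-free); vectorization counts fragment
occurrences per molecule against a frozen dictionary, silently dropping
fragments the dictionary has never seen (their number is logged).
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .structure_io import LigandMolecule

logger = logging.getLogger(__name__)

BOND_SYMBOLS = {1: "-", 2: "=", 3: "#"}


def _atom_symbol(mol: LigandMolecule, i: int) -> str:
    a = mol.atoms[i]
    return a.element.lower() if a.aromatic else a.element


def _bond_symbol(order: int, aromatic: bool) -> str:
    return ":" if aromatic else BOND_SYMBOLS.get(order, "-")


def enumerate_sequences(
    mol: LigandMolecule, min_atoms: int = 2, max_atoms: int = 6
) -> dict[str, int]:
    """Count every simple path of ``min_atoms``..``max_atoms`` heavy atoms.

    Each undirected path is counted once under its canonical label.
    A single-atom molecule yields an empty mapping.
    """
    adj = mol.adjacency()
    counts: Counter[str] = Counter()

    def extend(path: list[int], symbols: list[str]) -> None:
        if len(path) >= min_atoms:
            forward = "".join(symbols)
            backward = "".join(_reverse_render(symbols))
            counts[min(forward, backward)] += 1
        if len(path) == max_atoms:
            return
        tip = path[-1]
        on_path = set(path)
        for j, order, arom in adj[tip]:
            if j in on_path:
                continue
            extend(path + [j], symbols + [_bond_symbol(order, arom), _atom_symbol(mol, j)])

    for start in range(mol.n_atoms):
        extend([start], [_atom_symbol(mol, start)])

    # every undirected path was enumerated from both ends
    return {label: n // 2 for label, n in counts.items()}


def _reverse_render(symbols: list[str]) -> list[str]:
    return symbols[::-1]


def enumerate_augmented(mol: LigandMolecule) -> dict[str, int]:
    """Count augmented-atom fragments: centre + sorted bonded neighbours."""
    adj = mol.adjacency()
    counts: Counter[str] = Counter()
    for i in range(mol.n_atoms):
        terms = sorted(
            f"({_bond_symbol(order, arom)}{_atom_symbol(mol, j)})"
            for j, order, arom in adj[i]
        )
        counts[_atom_symbol(mol, i) + "".join(terms)] += 1
    return dict(counts)


def fragment_counts(mol: LigandMolecule) -> dict[str, int]:
    """Both fragment families for one molecule.

    Label sets of the two families are disjoint by construction (augmented
    labels of atoms with neighbours contain parentheses; a bare single-atom
    label cannot be a 2+-atom sequence), so a plain union is safe.
    """
    merged = dict(enumerate_sequences(mol))
    for label, n in enumerate_augmented(mol).items():
        merged[label] = merged.get(label, 0) + n
    return merged


@dataclass
class FragmentDictionary:
    """Canonical fragment label -> column index, frozen at training time."""

    entries: dict[str, int]
    source_size: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return sorted(self.entries, key=self.entries.get)

    def sha256(self) -> str:
        payload = json.dumps(self.entries, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {"entries": self.entries, "source_size": self.source_size},
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FragmentDictionary":
        data = json.loads(text)
        return cls(entries=data["entries"], source_size=data.get("source_size", 0))


def build_dictionary(mols: list[LigandMolecule]) -> FragmentDictionary:
    """Union of both fragment families over a molecule collection,
    lexicographically indexed (deterministic and order-invariant)."""
    if not mols:
        raise ValueError("cannot build a fragment dictionary from zero molecules")
    labels: set[str] = set()
    for mol in mols:
        labels.update(fragment_counts(mol))
    entries = {label: i for i, label in enumerate(sorted(labels))}
    return FragmentDictionary(entries=entries, source_size=len(mols))


@dataclass
class FragVector:
    """Per-ligand fragment counts against a fixed dictionary."""

    values: np.ndarray
    n_unseen: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)


def vectorize_fragments(
    mol: LigandMolecule, dictionary: FragmentDictionary
) -> FragVector:
    """Count a molecule's fragments in dictionary column order; fragments
    absent from the dictionary are dropped (their count is logged)."""
    values = np.zeros(len(dictionary), dtype=int)
    unseen = 0
    for label, n in fragment_counts(mol).items():
        idx = dictionary.entries.get(label)
        if idx is None:
            unseen += n
        else:
            values[idx] = n
    if unseen:
        logger.info(
            "%s: %d fragment occurrences not in the dictionary, dropped",
            mol.name, unseen,
        )
    return FragVector(values=values, n_unseen=unseen)
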