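"""Per-complex feature vectors, labeled datasets, and seeded splits.

Four feature sets are supported, always concatenated in the fixed order
fingerprint counts, interaction distances, fragment counts:

======================  =========================
name                    dimension
======================  =========================
``ifp``                 140
``ifp+dist``            280
``ifp+frag``            140 + dictionary size
``ifp+dist+frag``       280 + dictionary size
======================  =========================

Features are used raw by the random-forest learner; the deep network
standardizes them with training-set mean/variance (the constants travel
with the model).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentDictionary, FragVector, vectorize_fragments
from .interactions import (
    GeometricRules,
    IFP_FEATURE_NAMES,
    INTDIST_FEATURE_NAMES,
    IFPVector,
    IntDistVector,
    build_ifp,
    build_intdist,
    detect_interactions,
)
from .structure_io import ComplexRecord, LigandMolecule, ProteinStructure

#: canonical feature-set names -> (use_dist, use_frag)
FEATURE_SETS: dict[str, tuple[bool, bool]] = {
    "ifp": (False, False),
    "ifp+dist": (True, False),
    "ifp+frag": (False, True),
    "ifp+dist+frag": (True, True),
}

_ALIASES = {
    "ifp": "ifp",
    "ifp+int-dist": "ifp+dist",
    "ifp+dist": "ifp+dist",
    "ifp+frag": "ifp+frag",
    "ifp+int-dist+frag": "ifp+dist+frag",
    "ifp+dist+frag": "ifp+dist+frag",
}


def canonical_set_name(name: str) -> str:
    key = name.strip().lower()
    if key not in _ALIASES:
        raise ValueError(f"unknown feature set {name!r}; expected one of "
                         f"{sorted(FEATURE_SETS)}")
    return _ALIASES[key]


def feature_names(set_name: str, dictionary: FragmentDictionary | None = None
                  ) -> list[str]:
    use_dist, use_frag = FEATURE_SETS[canonical_set_name(set_name)]
    names = list(IFP_FEATURE_NAMES)
    if use_dist:
        names += list(INTDIST_FEATURE_NAMES)
    if use_frag:
        if dictionary is None:
            raise ValueError("fragment feature set requires a dictionary")
        names += [f"FRAG[{label}]" for label in dictionary.labels]
    return names


def assemble_features(
    ifp: IFPVector,
    intdist: IntDistVector | None,
    frag: FragVector | None,
    set_name: str,
) -> np.ndarray:
    """Concatenate the requested components into one feature row."""
    use_dist, use_frag = FEATURE_SETS[canonical_set_name(set_name)]
    parts = [np.asarray(ifp.values, dtype=float)]
    if use_dist:
        if intdist is None:
            raise ValueError("feature set requires the interaction-distance "
                             "component (intdist) but it is missing")
        parts.append(np.asarray(intdist.values, dtype=float))
    if use_frag:
        if frag is None:
            raise ValueError("feature set requires the fragment component "
                             "(frag) but it is missing")
        parts.append(np.asarray(frag.values, dtype=float))
    return np.concatenate(parts)


def featurize_complex(
    protein: ProteinStructure,
    ligand: LigandMolecule,
    set_name: str,
    dictionary: FragmentDictionary | None = None,
    rules: GeometricRules | None = None,
) -> np.ndarray:
    """Full featurization of one complex: detect, fold, fragment, concat."""
    records = detect_interactions(protein, ligand, rules)
    ifp = build_ifp(records)
    intdist = build_intdist(records)
    use_frag = FEATURE_SETS[canonical_set_name(set_name)][1]
    frag = vectorize_fragments(ligand, dictionary) if use_frag else None
    return assemble_features(ifp, intdist, frag, set_name)


@dataclass
class LabeledDataset:
    """Feature matrix + pKd/pKi labels for a set of complexes."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    feature_set: str = "ifp"
    feature_names: list[str] = field(default_factory=list)
    dictionary: FragmentDictionary | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == self.X.shape[0] == len(self.y)):
            raise ValueError("ids, features and labels must align row-wise")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("dataset contains missing values")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
            feature_set=self.feature_set,
            feature_names=self.feature_names,
            dictionary=self.dictionary,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_names or [f"f{i}" for i in range(self.X.shape[1])]
        df = pd.DataFrame(self.X, columns=cols, index=self.ids)
        df.insert(0, "affinity", self.y)
        return df

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index_label="id", float_format="%.6g")
        return buf.getvalue()


def dataset_from_complexes(
    records: list[ComplexRecord],
    set_name: str,
    dictionary: FragmentDictionary | None = None,
    rules: GeometricRules | None = None,
) -> LabeledDataset:
    """Featurize loaded complex records into one labeled dataset."""
    set_name = canonical_set_name(set_name)
    rows, ids, labels = [], [], []
    for rec in records:
        if rec.protein is None or rec.ligand is None or rec.affinity is None:
            raise ValueError(f"complex {rec.id}: structures/label not loaded")
        rows.append(featurize_complex(rec.protein, rec.ligand, set_name,
                                      dictionary, rules))
        ids.append(rec.id)
        labels.append(rec.affinity)
    return LabeledDataset(
        ids=ids,
        X=np.vstack(rows),
        y=np.array(labels),
        feature_set=set_name,
        feature_names=feature_names(set_name, dictionary),
        dictionary=dictionary,
    )


def split_dataset(
    ds: LabeledDataset, ratio: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive, seed-reproducible train/validation split."""
    if ds.n < 2:
        raise ValueError("need at least 2 rows to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    k = int(round(ds.n * ratio))
    k = min(max(k, 1), ds.n - 1)
    return ds.subset(np.sort(perm[:k])), ds.subset(np.sort(perm[k:]))


def remove_overlap(train_ids: list[str], test_ids: list[str]) -> list[str]:
    """Order-preserving removal of ids that also appear in the test set."""
    test = set(test_ids)
    return [i for i in train_ids if i not in test]


@dataclass
class Standardizer:
    """Train-set mean/std scaling used by the deep network."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        std = X.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean=X.mean(axis=0), std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=np.array(d["mean"]), std=np.array(d["std"]))


def split_manifest(seed: int, train: LabeledDataset, valid: LabeledDataset) -> str:
    return json.dumps(
        {"seed": seed, "train_ids": train.ids, "valid_ids": valid.ids}, indent=1
    )
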