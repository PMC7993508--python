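"""Atom typing, geometric interaction detection, and fingerprint folding."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ifpscore.interactions import (
    CLASSES,
    GeometricRules,
    InteractionRecord,
    N_CELLS,
    assign_atom_types,
    build_ifp,
    build_intdist,
    cell_index,
    detect_interactions,
    records_to_tsv,
    type_ligand,
)
from ifpscore.structure_io import STANDARD_AA, LigandAtom, LigandMolecule
from ifpscore.synthetic import PlantSpec, make_toy_complex, random_plant_spec
from oracles import brute_force_interactions, records_to_set


class TestTyping:
    def test_arginine_guanidinium_is_cationic(self):
        prot, _, _ = make_toy_complex(
            PlantSpec(planted=[("ARG", "IONIC_LIG_NEG", 3.0)]))
        typed = assign_atom_types(prot)[0]
        assert len(typed.cations) == 3  # NE, NH1, NH2

    def test_benzene_one_ring_six_hydrophobic(self, benzene):
        typed = type_ligand(benzene)
        assert len(typed.rings) == 1
        assert len(typed.hydrophobic) == 6
        assert len(typed.donors) == len(typed.acceptors) == 0

    def test_acetate_both_oxygens_anionic(self, acetate):
        typed = type_ligand(acetate)
        assert len(typed.anions) == 2
        # charged oxygens are ions, not H-bond acceptors
        assert len(typed.acceptors) == 0

    def test_hydroxyl_oxygen_is_donor_and_acceptor(self, ethanol):
        typed = type_ligand(ethanol)
        assert len(typed.donors) == 1
        assert len(typed.acceptors) == 1
        assert len(typed.hydrophobic) == 1  # only the methyl carbon

    def test_unsupported_structure_type(self):
        with pytest.raises(TypeError):
            assign_atom_types(42)


class TestDetect:
    def test_planted_ionic_contact_at_exact_distance(self):
        prot, lig, _ = make_toy_complex(
            PlantSpec(planted=[("ARG", "IONIC_LIG_NEG", 3.0)]))
        recs = detect_interactions(prot, lig)
        assert len(recs) == 1
        r = recs[0]
        assert (r.residue_name, r.interaction_class) == ("ARG", "IONIC_LIG_NEG")
        assert np.isclose(r.distance, 3.0, atol=1e-9)

    def test_planted_face_to_face_stack(self):
        prot, lig, _ = make_toy_complex(
            PlantSpec(planted=[("PHE", "AR_F2F", 3.6)]))
        recs = detect_interactions(prot, lig)
        f2f = [r for r in recs if r.interaction_class == "AR_F2F"]
        assert len(f2f) == 1
        assert f2f[0].residue_name == "PHE"
        assert np.isclose(f2f[0].distance, 3.6, atol=1e-9)

    def test_distant_ligand_yields_nothing(self):
        prot, lig, _ = make_toy_complex(
            PlantSpec(planted=[("SER", "HBOND_ACC_LIG", 3.0)]))
        far = LigandMolecule(
            atoms=[dataclasses.replace(a, coord=a.coord + np.array([0, 0, -200.0]))
                   for a in lig.atoms],
            bonds=lig.bonds)
        assert detect_interactions(prot, far) == []

    def test_rigid_motion_invariance(self):
        spec = random_plant_spec(11)
        prot, lig, _ = make_toy_complex(spec)
        base = build_intdist(detect_interactions(prot, lig)).values

        rot = Rotation.from_euler("xyz", [31, -54, 17], degrees=True)
        shift = np.array([5.0, -3.0, 11.0])
        for res in prot.residues:
            for a in res.atoms:
                a.coord = rot.apply(a.coord) + shift
        moved = LigandMolecule(
            atoms=[dataclasses.replace(a, coord=rot.apply(a.coord) + shift)
                   for a in lig.atoms],
            bonds=lig.bonds)
        after = build_intdist(detect_interactions(prot, moved)).values
        assert np.allclose(base, after, atol=1e-6)

    def test_input_order_invariance(self):
        spec = random_plant_spec(23)
        prot, lig, _ = make_toy_complex(spec)
        base = build_ifp(detect_interactions(prot, lig)).values

        rng = np.random.default_rng(0)
        prot.residues = [prot.residues[i]
                         for i in rng.permutation(len(prot.residues))]
        perm = rng.permutation(lig.n_atoms)
        inv = np.argsort(perm)
        shuffled = LigandMolecule(
            atoms=[lig.atoms[i] for i in perm],
            bonds=[(int(inv[i]), int(inv[j]), o, a) for i, j, o, a in lig.bonds])
        after = build_ifp(detect_interactions(prot, shuffled)).values
        assert np.array_equal(base, after)

    @pytest.mark.parametrize("seed", range(8))
    def test_shrinking_cutoffs_never_adds_interactions(self, seed):
        prot, lig, _ = make_toy_complex(random_plant_spec(seed))
        wide = GeometricRules()
        narrow = GeometricRules(
            hydrophobic_cutoff=3.8, f2f_centroid_cutoff=3.5,
            e2f_centroid_cutoff=5.0, hbond_da_cutoff=3.0, ionic_cutoff=3.2)
        v_wide = build_ifp(detect_interactions(prot, lig, wide)).values
        v_narrow = build_ifp(detect_interactions(prot, lig, narrow)).values
        assert np.all(v_narrow <= v_wide)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        prot, lig, _ = make_toy_complex(random_plant_spec(seed))
        got = records_to_set(detect_interactions(prot, lig))
        want = brute_force_interactions(prot, lig)
        assert got == want


def _rec(name, cls, dist, number=1):
    return InteractionRecord(residue_name=name, residue_id=("A", number),
                             interaction_class=cls, distance=dist)


class TestFolding:
    def test_two_residues_of_same_name_sum(self):
        recs = [_rec("ARG", "HBOND_ACC_LIG", 2.9, 45),
                _rec("ARG", "HBOND_ACC_LIG", 3.2, 102)]
        ifp = build_ifp(recs)
        assert ifp.values[cell_index("ARG", "HBOND_ACC_LIG")] == 2
        assert ifp.values.sum() == 2

    def test_empty_records_give_zero_vectors(self):
        assert build_ifp([]).values.sum() == 0
        assert build_intdist([]).values.sum() == 0.0

    def test_vector_sum_equals_record_count(self):
        rng = np.random.default_rng(4)
        recs = [
            _rec(str(rng.choice(STANDARD_AA)), str(rng.choice(CLASSES)),
                 float(rng.uniform(2, 5)), n)
            for n in range(37)
        ]
        assert build_ifp(recs).values.sum() == len(recs)

    def test_intdist_keeps_minimum_distance(self):
        recs = [_rec("ARG", "HBOND_ACC_LIG", 2.9, 45),
                _rec("ARG", "HBOND_ACC_LIG", 3.2, 102)]
        v = build_intdist(recs).values
        assert v[cell_index("ARG", "HBOND_ACC_LIG")] == pytest.approx(2.9)
        assert np.count_nonzero(v) == 1

    def test_nonstandard_residue_is_skipped(self):
        recs = [_rec("MSE", "HYDROPHOBIC", 4.0)]
        assert build_ifp(recs).values.sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_count_distance_support_match(self, seed):
        prot, lig, _ = make_toy_complex(random_plant_spec(seed + 100))
        recs = detect_interactions(prot, lig)
        counts = build_ifp(recs).values
        dists = build_intdist(recs).values
        assert np.array_equal(counts > 0, dists > 0)

    def test_vector_length_is_enforced(self):
        from ifpscore.interactions import IFPVector
        with pytest.raises(ValueError):
            IFPVector(np.zeros(139))
        assert N_CELLS == len(STANDARD_AA) * len(CLASSES)


def test_profile_tsv_lists_each_record():
    prot, lig, _ = make_toy_complex(
        PlantSpec(planted=[("ARG", "IONIC_LIG_NEG", 3.0),
                           ("LEU", "HYDROPHOBIC", 4.0)]))
    tsv = records_to_tsv(detect_interactions(prot, lig))
    lines = tsv.strip().splitlines()
    assert lines[0].startswith("chain\t")
    assert len(lines) == 3
    assert any("IONIC_LIG_NEG" in ln for ln in lines)
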