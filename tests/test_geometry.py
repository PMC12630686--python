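import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glueprint.errors import (
    CorrespondenceError,
    DegenerateGeometryError,
    LigandCountError,
    PreconditionError,
)
from glueprint.geometry import (
    ContactCriteria,
    best_fit_plane,
    coarse_grain_beads,
    find_polar_contacts,
    kirkwood_rh,
    ligand_pair_rmsd,
    plane_angle,
    predict_rh,
    superpose,
    superpose_by_selection,
)
from glueprint.structure_io import StructureModel, assign_radii
from glueprint.synth import (
    RigidDimerSpec,
    make_rigid_dimer,
    make_ring_pair,
    rotation_about_axis,
)

from conftest import pseudo_atom


def brute_force_kirkwood(centers, radii):
    """Independent double-loop evaluation of the bead double sum."""
    n = len(centers)
    if n == 1:
        return float(radii[0])
    total = 0.0
    for i in range(n):
        total += 1.0 / radii[i]
        for j in range(n):
            if i != j:
                total += 1.0 / np.linalg.norm(
                    np.asarray(centers[i]) - np.asarray(centers[j]))
    return n * n / total


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 3))
        res = superpose(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        rot = rotation_about_axis([1, 1, 0], 63.0)
        b = a @ rot.T + np.array([3.0, -1.0, 2.0])
        res = superpose(a, b)
        assert res.rmsd < 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_oracle_with_noise(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(42)
        a = rng.normal(size=(30, 3)) * 2.0
        rot = rotation_about_axis([0, 1, 1], 25.0)
        b = a @ rot.T + 1.0 + rng.normal(scale=0.1, size=(30, 3))
        res = superpose(a, b)
        # independent code path: scipy's own Kabsch
        r_s, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        rmsd_oracle = rssd / np.sqrt(len(a))
        assert res.rmsd == pytest.approx(rmsd_oracle, abs=1e-9)
        assert res.rmsd == pytest.approx(0.1 * np.sqrt(3), rel=0.15)

    def test_symmetry_of_rmsd(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.2, size=(8, 3))
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd,
                                                     abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)

    def test_reflection_not_allowed(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(15, 3))
        b = a * np.array([-1.0, 1.0, 1.0])    # mirror image
        res = superpose(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1


class TestLigandPairRmsd:
    def test_identical_copies_zero(self):
        spec = RigidDimerSpec(n_atoms=20,
                              rotation=rotation_about_axis([0, 0, 1], 120.0),
                              translation=np.array([8.0, 0.0, 0.0]))
        model = make_rigid_dimer(spec)
        assert ligand_pair_rmsd(model, "LIG").rmsd < 1e-9

    def test_noisy_copies_match_bruteforce(self):
        from scipy.spatial.transform import Rotation
        spec = RigidDimerSpec(n_atoms=30,
                              rotation=rotation_about_axis([1, 0, 1], 77.0),
                              translation=np.array([5.0, 5.0, 0.0]),
                              noise_sigma=0.05, seed=11)
        model = make_rigid_dimer(spec)
        res = ligand_pair_rmsd(model, "LIG")
        a = np.array([a.position for a in model.atoms if a.chain_id == "A"])
        b = np.array([a.position for a in model.atoms if a.chain_id == "B"])
        _, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)

    def test_wrong_copy_count(self):
        model = StructureModel(atoms=[
            pseudo_atom(1, "A", [0, 0, 0], residue_name="LIG",
                        is_ligand=True)],
            ligand_codes=frozenset({"LIG"}))
        with pytest.raises(LigandCountError):
            ligand_pair_rmsd(model, "LIG")

    def test_name_mismatch_lists_offender(self):
        atoms = []
        for i, chain in enumerate(["A", "B"]):
            for j in range(4):
                name = f"L{j}" if not (chain == "B" and j == 3) else "WRONG"
                atoms.append(pseudo_atom(4 * i + j + 1, chain,
                                         [j * 1.5, i * 10.0, j % 2],
                                         name=name, residue_name="LIG",
                                         is_ligand=True))
        model = StructureModel(atoms=atoms, ligand_codes=frozenset({"LIG"}))
        with pytest.raises(CorrespondenceError, match="L3"):
            ligand_pair_rmsd(model, "LIG")


class TestPlanes:
    def test_square_is_planar(self):
        square = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        fit = best_fit_plane(square)
        assert fit.planarity_rms == pytest.approx(0.0, abs=1e-12)
        assert abs(fit.normal[2]) == pytest.approx(1.0, abs=1e-12)

    def test_three_points_exact(self):
        fit = best_fit_plane(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 3]]))
        assert fit.planarity_rms == pytest.approx(0.0, abs=1e-12)

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            best_fit_plane(np.outer(np.arange(4.0), [1.0, 1.0, 0]))

    def test_puckered_ring_rms(self):
        # regular pentagon with alternating out-of-plane offsets ±delta
        delta = 0.07
        ang = 2 * np.pi * np.arange(5) / 5
        pts = np.column_stack([np.cos(ang), np.sin(ang),
                               delta * np.array([1, -1, 1, -1, 1.0])])
        fit = best_fit_plane(pts)
        # plane stays z = const by symmetry of x/y; rms from construction
        z = pts[:, 2] - pts[:, 2].mean()
        assert fit.planarity_rms <= np.sqrt(np.mean(z ** 2)) + 1e-9
        assert fit.planarity_rms > 0.9 * delta / 2

    @pytest.mark.parametrize("angle", [0.0, 30.0, 45.0, 81.0, 90.0])
    def test_constructed_dihedral_recovered(self, angle):
        ring_a, ring_b = make_ring_pair(angle)
        got = plane_angle(best_fit_plane(ring_a), best_fit_plane(ring_b))
        assert got == pytest.approx(angle, abs=1e-6)

    def test_angle_sign_invariant(self):
        ring_a, ring_b = make_ring_pair(30.0)
        fa, fb = best_fit_plane(ring_a), best_fit_plane(ring_b)
        fb_flipped = best_fit_plane(ring_b[::-1])
        assert plane_angle(fa, fb) == pytest.approx(
            plane_angle(fa, fb_flipped), abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=90.0))
    @settings(max_examples=25, deadline=None)
    def test_angle_in_range_property(self, angle):
        ring_a, ring_b = make_ring_pair(angle)
        got = plane_angle(best_fit_plane(ring_a), best_fit_plane(ring_b))
        assert 0.0 <= got <= 90.0
        assert got == pytest.approx(angle, abs=1e-6)


class TestContacts:
    def _pair_model(self, distance, el_a="N", el_b="O"):
        return StructureModel(atoms=[
            pseudo_atom(1, "A", [0, 0, 0], element=el_a, residue_name="LIG",
                        is_ligand=True, name="N1"),
            pseudo_atom(2, "B", [distance, 0, 0], element=el_b,
                        residue_name="LIG", is_ligand=True, name="O1",
                        residue_seq=2),
        ], ligand_codes=frozenset({"LIG"}))

    def test_canonical_hbond(self):
        model = self._pair_model(2.9)
        recs = find_polar_contacts(model, np.array([True, False]),
                                   np.array([False, True]))
        assert len(recs) == 1
        assert recs[0].kind == "canonical_hbond"
        assert recs[0].cis_trans == "trans"

    def test_weak_band(self):
        recs = find_polar_contacts(self._pair_model(3.8),
                                   np.array([True, False]),
                                   np.array([False, True]))
        assert [r.kind for r in recs] == ["weak_hbond"]

    def test_far_pair_no_contact(self):
        recs = find_polar_contacts(self._pair_model(5.0),
                                   np.array([True, False]),
                                   np.array([False, True]))
        assert recs == []

    def test_ch_o_contact(self):
        model = self._pair_model(3.4, el_a="C", el_b="O")
        recs = find_polar_contacts(model, np.array([True, False]),
                                   np.array([False, True]))
        assert [r.kind for r in recs] == ["ch_o_contact"]

    def test_empty_selection_rejected(self):
        model = self._pair_model(2.9)
        with pytest.raises(PreconditionError):
            find_polar_contacts(model, np.array([False, False]),
                                np.array([False, True]))

    def test_symmetric_in_selection_order(self):
        model = self._pair_model(2.9)
        a = np.array([True, False])
        b = np.array([False, True])
        r1 = find_polar_contacts(model, a, b)
        r2 = find_polar_contacts(model, b, a)
        assert [(r.kind, round(r.distance, 9)) for r in r1] == \
               [(r.kind, round(r.distance, 9)) for r in r2]

    def test_count_monotone_in_cutoffs(self):
        rng = np.random.default_rng(5)
        atoms = []
        for i in range(20):
            chain = "A" if i < 10 else "B"
            el = "N" if i % 2 else "O"
            atoms.append(pseudo_atom(i + 1, chain,
                                     rng.uniform(-4, 4, 3), element=el,
                                     residue_name="LIG", is_ligand=True,
                                     name=f"X{i}", residue_seq=i + 1))
        model = StructureModel(atoms=atoms, ligand_codes=frozenset({"LIG"}))
        sel_a = np.array([a.chain_id == "A" for a in model.atoms])
        sel_b = ~sel_a
        prev = -1
        for cut in [2.5, 3.0, 3.5, 4.0]:
            crit = ContactCriteria(canonical_max=cut, weak_max=cut,
                                   ch_o_max=cut)
            n = len(find_polar_contacts(model, sel_a, sel_b, crit))
            assert n >= prev
            prev = n

    def test_protein_typing_rules(self):
        # backbone N donates to backbone O across chains
        model = StructureModel(atoms=[
            pseudo_atom(1, "A", [0, 0, 0], element="N", name="N",
                        residue_name="GLY"),
            pseudo_atom(2, "B", [3.0, 0, 0], element="O", name="O",
                        residue_name="ALA"),
            pseudo_atom(3, "B", [0, 3.0, 0], element="C", name="CB",
                        residue_name="ALA", residue_seq=2),
        ])
        sel_a = np.array([True, False, False])
        sel_b = np.array([False, True, True])
        recs = find_polar_contacts(model, sel_a, sel_b)
        assert [r.kind for r in recs] == ["canonical_hbond"]
        assert recs[0].donor_atom.name == "N"


class TestSuperposeBySelection:
    def test_copy_gives_zero(self):
        rng = np.random.default_rng(8)
        atoms = [pseudo_atom(i + 1, "A", rng.normal(size=3) * 3.0,
                             name="CA", residue_name="GLY", residue_seq=i + 1)
                 for i in range(10)]
        model = StructureModel(atoms=atoms)
        residues = [("A", i + 1) for i in range(10)]
        res, moved = superpose_by_selection(model, model, residues, residues)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_applied_transform(self):
        import dataclasses
        rng = np.random.default_rng(9)
        atoms = [pseudo_atom(i + 1, "A", rng.normal(size=3) * 3.0,
                             name="CA", residue_name="GLY", residue_seq=i + 1)
                 for i in range(10)]
        model_a = StructureModel(atoms=atoms)
        rot = rotation_about_axis([2, 1, 0], 40.0)
        shift = np.array([1.0, 2.0, 3.0])
        model_b = StructureModel(atoms=[
            dataclasses.replace(a, position=rot @ a.position + shift)
            for a in atoms])
        residues = [("A", i + 1) for i in range(10)]
        res, moved = superpose_by_selection(model_a, model_b,
                                            residues, residues)
        assert res.rmsd < 1e-9
        # recovered transform must invert the applied one
        assert np.allclose(res.rotation, rot.T, atol=1e-9)
        assert np.allclose(moved.coords(), model_a.coords(), atol=1e-9)

    def test_unequal_selection_lengths(self, toy_dimer):
        model, _ = toy_dimer
        with pytest.raises(CorrespondenceError):
            superpose_by_selection(model, model, [("A", 1)], [])


class TestRh:
    def test_single_bead(self):
        m = assign_radii(StructureModel(atoms=[
            pseudo_atom(1, "A", [0, 0, 0], residue_name="LIG",
                        is_ligand=True)], ligand_codes=frozenset({"LIG"})))
        est = predict_rh(m, hydration=3.0)
        assert est.rh == pytest.approx((1.7 + 3.0) / 10.0, abs=1e-12)
        assert est.n_beads == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        centers = rng.normal(size=(40, 3)) * 10.0
        radii = rng.uniform(2.0, 5.0, size=40)
        assert kirkwood_rh(centers, radii) == pytest.approx(
            brute_force_kirkwood(centers, radii), abs=1e-9)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(18)
        centers = rng.normal(size=(25, 3)) * 8.0
        radii = rng.uniform(2.0, 4.0, size=25)
        rot = rotation_about_axis([1, 3, 2], 51.0)
        moved = centers @ rot.T + np.array([10.0, -4.0, 2.0])
        assert kirkwood_rh(moved, radii) == pytest.approx(
            kirkwood_rh(centers, radii), rel=1e-12)

    def test_grows_when_beads_spread(self):
        rng = np.random.default_rng(19)
        centers = rng.normal(size=(20, 3)) * 5.0
        radii = np.full(20, 3.0)
        r1 = kirkwood_rh(centers, radii)
        r2 = kirkwood_rh(centers * 2.0, radii)
        assert r2 > r1

    def test_coarse_graining_counts(self, toy_dimer):
        model, _ = toy_dimer
        centers, radii = coarse_grain_beads(model)
        n_lig = int(model.ligand_mask().sum())
        n_res = len({(a.chain_id, a.residue_seq) for a in model.atoms
                     if not a.is_ligand})
        assert len(centers) == n_lig + n_res

    def test_radii_required(self):
        m = StructureModel(atoms=[pseudo_atom(1, "A", [0, 0, 0],
                                              radius=-1.0)])
        with pytest.raises(PreconditionError):
            predict_rh(m)
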