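"""Similarity measures: fps worked example, Kabsch vs quaternion oracle,
L_rms / I_rms behavior and invariances."""

import math

import numpy as np
import pytest

from ppivar.model import HeteroDimer
from ppivar.similarity import (
    SuperpositionError,
    combine_sides,
    common_residues,
    face_position_similarity,
    i_rms,
    kabsch_superpose,
    l_rms,
    similarity_record,
)
from ppivar.synthetic import build_chain, dock, make_variants, transform_chain

from conftest import FAST, make_dimer, random_rigid


def quaternion_superpose(a, b):
    """Independent closed-form oracle (Horn's quaternion method) for the
    optimal proper rotation; returns the minimized RMSD."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    w, x, y, z = eigvecs[:, -1]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    moved = b @ rot.T
    return rot, float(np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1))))


class TestFacePositionSimilarity:
    def test_worked_example(self):
        """Faces {1,2,3} vs {1,3,7,8}: 2 shared positions over the geometric
        mean sqrt(3*4) ~ 3.5 gives 2/3.5 ~ 0.577."""
        identity = {i: i for i in range(1, 10)}
        value = face_position_similarity({1, 2, 3}, {1, 3, 7, 8}, identity)
        assert value == pytest.approx(2 / math.sqrt(12), abs=1e-12)
        assert round(math.sqrt(3 * 4), 1) == 3.5
        assert value == pytest.approx(2 / 3.5, abs=0.01)

    def test_identical_faces(self):
        identity = {i: i for i in range(1, 10)}
        assert face_position_similarity({2, 3, 4}, {2, 3, 4}, identity) == 1.0

    def test_disjoint_faces(self):
        identity = {i: i for i in range(1, 10)}
        assert face_position_similarity({1, 2}, {8, 9}, identity) == 0.0

    def test_empty_face_after_reduction_is_undefined(self):
        assert face_position_similarity({1, 2}, {1, 2}, {5: 5}) is None

    def test_shrinking_intersection_never_increases(self):
        identity = {i: i for i in range(1, 30)}
        face_a = set(range(1, 11))
        face_b = set(range(5, 16))
        base = face_position_similarity(face_a, face_b, identity)
        for shared in sorted(face_a & face_b):
            smaller = face_position_similarity(
                face_a - {shared}, face_b, identity
            )
            assert smaller <= base + 1e-12

    @pytest.mark.parametrize(
        "fx,fy,expected", [(1.0, 1.0, 1.0), (0.0, 1.0, 0.5), (0.6, 0.8, 0.7)]
    )
    def test_combine_sides_is_mean(self, fx, fy, expected):
        assert combine_sides(fx, fy) == pytest.approx(expected)


class TestCommonResidues:
    def test_identical_sequences_identity_map(self, mode_dimers):
        corr = common_residues(mode_dimers["m0"], mode_dimers["m0_bis"])
        assert corr.coverage == 1.0
        assert all(k == v for k, v in corr.mapX.items())
        assert len(corr.mapX) == 60

    def test_unresolved_positions_excluded(self, rod_chains, two_modes):
        cx, cy = rod_chains
        d1 = make_dimer(cx, cy, two_modes[0], assembly_id="u1")
        d2 = make_dimer(cx, cy, two_modes[0], assembly_id="u2")
        for res in d2.chainX.residues:
            if res.seqres_index in (5, 6, 7, 8, 9):
                res.atoms = []
        corr = common_residues(d1, d2)
        assert set(corr.mapX) == set(range(1, 61)) - {5, 6, 7, 8, 9}

    def test_point_mutation_keeps_identity_map(self, rod_chains, two_modes):
        cx, cy = rod_chains
        mutant = make_variants(cx, "point_mutation", 0.05, seed=41)
        d1 = make_dimer(cx, cy, two_modes[0], assembly_id="v1")
        d2 = make_dimer(mutant, cy, two_modes[0], assembly_id="v2")
        corr = common_residues(d1, d2)
        assert corr.coverage == 1.0
        assert all(k == v for k, v in corr.mapX.items())


class TestKabsch:
    def test_exact_recovery_of_rigid_copy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        rot, shift = random_rigid(2)
        b = (a - shift) @ rot  # inverse transform
        matrix, trans, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(b @ matrix.T + trans, a, atol=1e-8)

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_quaternion_oracle(self, seed):
        """100 seeded noisy point sets: Kabsch and the quaternion method
        agree to 1e-6 A."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        a = rng.normal(size=(n, 3)) * 10
        rot, shift = random_rigid(seed + 1000)
        b = (a @ rot + shift) + rng.normal(scale=0.5, size=(n, 3))
        _, _, rmsd = kabsch_superpose(a, b)
        _, oracle_rmsd = quaternion_superpose(a, b)
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-6)

    def test_mirror_image_gets_proper_rotation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 3))
        b = a * np.array([1.0, 1.0, -1.0])  # reflection
        matrix, _, rmsd = kabsch_superpose(a, b)
        assert np.linalg.det(matrix) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1
        _, oracle_rmsd = quaternion_superpose(a, b)
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-6)

    def test_degenerate_inputs_raise(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(SuperpositionError):
            kabsch_superpose(line, line)
        with pytest.raises(SuperpositionError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsMeasures:
    def test_rigid_copy_has_zero_l_and_i_rms(self, rod_chains, two_modes):
        cx, cy = rod_chains
        d1 = make_dimer(cx, cy, two_modes[0], assembly_id="r1")
        d2 = make_dimer(
            cx, cy, two_modes[0], assembly_id="r2", rigid=random_rigid(51)
        )
        corr = common_residues(d1, d2)
        assert l_rms(d1, d2, corr) == pytest.approx(0.0, abs=1e-6)
        assert i_rms(d1, d2, corr) == pytest.approx(0.0, abs=1e-6)

    def test_l_rms_matches_two_step_oracle(self, rod_chains, two_modes):
        """Independent naive recomputation: superpose receptors, move the
        ligand, take the backbone RMSD."""
        cx, cy = rod_chains
        d1 = make_dimer(cx, cy, two_modes[0], assembly_id="o1")
        d2 = make_dimer(cx, cy, two_modes[1], assembly_id="o2")
        corr = common_residues(d1, d2)
        value = l_rms(d1, d2, corr)

        def backbone(chain, positions):
            out = []
            for pos in sorted(positions):
                res = chain.residue_at(pos)
                atoms = {a.name: a.coord for a in res.atoms}
                out.extend(atoms[n] for n in ("N", "CA", "C", "O") if n in atoms)
            return np.array(out)

        # receptor is X by the tie rule (equal lengths, accX < accY)
        rec_a = backbone(d1.chainX, corr.mapX)
        rec_b = backbone(d2.chainX, [corr.mapX[p] for p in corr.mapX])
        rot, oracle_rmsd = quaternion_superpose(rec_a, rec_b)
        lig_a = backbone(d1.chainY, corr.mapY)
        lig_b = backbone(d2.chainY, [corr.mapY[p] for p in corr.mapY])
        # full transform: rotate about receptor centroids then translate
        cen_a = rec_a.mean(axis=0)
        cen_b = rec_b.mean(axis=0)
        lig_moved = (lig_b - cen_b) @ rot.T + cen_a
        oracle = float(
            np.sqrt(np.mean(np.sum((lig_a - lig_moved) ** 2, axis=1)))
        )
        assert value == pytest.approx(oracle, abs=1e-6)

    def test_hinge_bend_gives_positive_l_rms_at_full_fps(
        self, rod_chains, two_modes
    ):
        """A ligand conformational change away from the binding site leaves
        the faces identical but L_rms positive."""
        cx, cy = rod_chains
        d1 = make_dimer(cx, cy, two_modes[0], assembly_id="h1")
        d2 = make_dimer(cx, cy, two_modes[0], assembly_id="h2")
        # bend the ligand (Y) tail far from the mode-0 window (residues >= 45)
        from scipy.spatial.transform import Rotation

        hinge = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        pivot = None
        for res in d2.chainY.residues:
            if res.seqres_index == 45:
                pivot = next(a.coord for a in res.atoms if a.name == "CA")
        for res in d2.chainY.residues:
            if res.seqres_index > 45:
                for atom in res.atoms:
                    atom.coord = hinge @ (atom.coord - pivot) + pivot
        rec = similarity_record(d1, d2)
        assert rec.fps == 1.0
        assert rec.l_rms > 0.5

    def test_i_rms_detects_interface_reshaping(self, rod_chains, two_modes):
        """Rotating the ligand within the same site leaves a positive
        interface RMSD, equal to a direct superposition oracle."""
        cx, cy = rod_chains
        d1 = make_dimer(cx, cy, two_modes[0], assembly_id="s1")
        d2 = make_dimer(cx, cy, two_modes[0], assembly_id="s2")
        from scipy.spatial.transform import Rotation

        spin = Rotation.from_euler("x", 12, degrees=True).as_matrix()
        center = d2.chainY.atom_coords().mean(axis=0)
        for res in d2.chainY.residues:
            for atom in res.atoms:
                atom.coord = spin @ (atom.coord - center) + center
        d2.interface = d1.interface  # same annotated region on both
        corr = common_residues(d1, d2)
        value = i_rms(d1, d2, corr)
        assert value is not None and value > 0.05

        rows_a, rows_b = [], []
        for side, chain_a, chain_b in (
            ("X", d1.chainX, d2.chainX),
            ("Y", d1.chainY, d2.chainY),
        ):
            region = set(d1.interface.face(side)) | set(d2.interface.face(side))
            for pos in sorted(region):
                ra = {a.name: a.coord for a in chain_a.residue_at(pos).atoms}
                rb = {a.name: a.coord for a in chain_b.residue_at(pos).atoms}
                for name in ("N", "CA", "C", "O"):
                    rows_a.append(ra[name])
                    rows_b.append(rb[name])
        _, oracle = quaternion_superpose(np.array(rows_a), np.array(rows_b))
        assert value == pytest.approx(oracle, abs=1e-6)

    def test_measures_invariant_under_rigid_motion(self, rod_chains, two_modes):
        cx, cy = rod_chains
        d1 = make_dimer(cx, cy, two_modes[0], assembly_id="i1")
        d2 = make_dimer(cx, cy, two_modes[1], assembly_id="i2")
        d2_moved = make_dimer(
            cx, cy, two_modes[1], assembly_id="i2", rigid=random_rigid(61)
        )
        base = similarity_record(d1, d2)
        moved = similarity_record(d1, d2_moved)
        assert moved.fps == pytest.approx(base.fps, abs=1e-9)
        assert moved.l_rms == pytest.approx(base.l_rms, abs=1e-6)
        assert moved.i_rms == pytest.approx(base.i_rms, abs=1e-6)

    def test_symmetry_in_pair_order(self, mode_dimers):
        ab = similarity_record(mode_dimers["m0"], mode_dimers["m1"])
        ba = similarity_record(mode_dimers["m1"], mode_dimers["m0"])
        assert ab.fps == pytest.approx(ba.fps, abs=1e-12)
        assert ab.l_rms == pytest.approx(ba.l_rms, abs=1e-6)
        assert ab.i_rms == pytest.approx(ba.i_rms, abs=1e-6)

    def test_self_similarity(self, mode_dimers):
        rec = similarity_record(mode_dimers["m0"], mode_dimers["m0_bis"])
        assert rec.fps == 1.0
        assert rec.l_rms == pytest.approx(0.0, abs=1e-6)
        assert rec.i_rms == pytest.approx(0.0, abs=1e-6)
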