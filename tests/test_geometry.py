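"""Internal-coordinate geometry: dihedrals, chain building, superposition."""

import numpy as np
import pytest

from macpep import topology as topo
from macpep.exceptions import (AtomMappingError, GeometryError,
                               InsufficientPointsError, InvalidTorsionError)
from macpep.geometry import (PeptidePose, TorsionSet, build_chain,
                             measure_dihedral, pose_rmsd, random_rotation,
                             superpose_kabsch, wrap_angle)


def _random_torsions(rng, n, identity="ALA"):
    return [TorsionSet(float(rng.uniform(-180, 180)),
                       float(rng.uniform(-180, 180)), 180.0, ()) for _ in range(n)]


def _oracle_dihedral(p1, p2, p3, p4):
    """Independent formulation: angle between plane normals, signed by the
    determinant of (b1, b2, b3)."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.linalg.det(np.array([b1, b2, b3])) < 0:
        ang = -ang
    return wrap_angle(ang)


class TestMeasureDihedral:
    def test_trans_planar_points(self):
        pts = map(np.array, ([0, 1, 0.0], [0, 0, 0], [1, 0, 0], [1, -1, 0]))
        assert measure_dihedral(*pts) == pytest.approx(180.0)

    def test_cis_planar_points(self):
        pts = map(np.array, ([0, 1, 0.0], [0, 0, 0], [1, 0, 0], [1, 1, 0]))
        assert measure_dihedral(*pts) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                mine = measure_dihedral(*pts)
            except GeometryError:
                continue
            assert abs(wrap_angle(mine - _oracle_dihedral(*pts))) < 1e-9

    def test_collinear_raises(self):
        with pytest.raises(GeometryError):
            measure_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(4, 3)) * 2.0
        ref = measure_dihedral(*pts)
        for _ in range(20):
            R = random_rotation(rng)
            t = rng.normal(size=3) * 10
            moved = pts @ R.T + t
            assert abs(wrap_angle(measure_dihedral(*moved) - ref)) < 1e-9

    def test_mirror_antisymmetry(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 2.0
            try:
                d = measure_dihedral(*pts)
            except GeometryError:
                continue
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert abs(wrap_angle(measure_dihedral(*mirrored) + d)) < 1e-9


class TestBuildChain:
    def test_torsion_round_trip(self, rng):
        # 100 chains x ~9 torsion pairs ≈ 1000 random torsions
        for _ in range(100):
            tors = _random_torsions(rng, 6)
            pose = build_chain(["ALA"] * 6, tors)
            for i in range(6):
                if i > 0:
                    assert abs(wrap_angle(pose.phi(i) - tors[i].phi)) < 1e-6
                if i < 5:
                    assert abs(wrap_angle(pose.psi(i) - tors[i].psi)) < 1e-6

    def test_extended_ca_ca_distance(self):
        tors = [TorsionSet(180, 180, 180, ()) for _ in range(5)]
        pose = build_chain(["GLY"] * 5, tors)
        for i in range(4):
            d = np.linalg.norm(pose.residues[i + 1].atoms["CA"]
                               - pose.residues[i].atoms["CA"])
            assert d == pytest.approx(3.80, abs=0.02)

    def test_ideal_bond_geometry(self, rng):
        tors = _random_torsions(rng, 4)
        pose = build_chain(["GLY"] * 4, tors)
        for i in range(4):
            r = pose.residues[i].atoms
            assert np.linalg.norm(r["CA"] - r["N"]) == pytest.approx(topo.BOND_N_CA, abs=1e-8)
            assert np.linalg.norm(r["C"] - r["CA"]) == pytest.approx(topo.BOND_CA_C, abs=1e-8)
            if i > 0:
                prev = pose.residues[i - 1].atoms
                assert np.linalg.norm(r["N"] - prev["C"]) == pytest.approx(
                    topo.BOND_C_N, abs=1e-8)

    def test_nine_residue_anchor_plus_arms(self):
        # a hotspot with 4 Gly appended to either terminus gives a 9-mer
        tors = [TorsionSet(180, 180, 180, ()) for _ in range(9)]
        tops = ["GLY"] * 4 + ["TYR"] + ["GLY"] * 4
        pose = build_chain(tops, tors)
        assert len(pose) == 9 and not pose.cyclic
        assert pose.residues[4].identity == "TYR"

    def test_anchored_bidirectional_growth(self, rng):
        tors = _random_torsions(rng, 7)
        free = build_chain(["ALA"] * 7, tors)
        anchor = {k: free.residues[3].atoms[k] for k in ("N", "CA", "C")}
        pose = build_chain(["ALA"] * 7, tors, anchor=anchor, anchor_index=3)
        for k, v in anchor.items():
            assert np.array_equal(pose.residues[3].atoms[k], v)
        for i in range(7):
            if i > 0:
                assert abs(wrap_angle(pose.phi(i) - tors[i].phi)) < 1e-6

    def test_chi_for_gly_raises(self):
        tors = [TorsionSet(180, 180, 180, (60.0,))]
        with pytest.raises(InvalidTorsionError):
            build_chain(["GLY"], tors)

    def test_d_l_mirror_chains(self, rng):
        for identity in ("SER", "LEU", "TYR", "PRO"):
            chis = tuple([-60.0] * topo.get_topology(identity).n_chi)
            torsL = [TorsionSet(-70, -40, 180, chis) for _ in range(3)]
            torsD = [TorsionSet(70, 40, 180, tuple(-c for c in chis))
                     for _ in range(3)]
            pL = build_chain([identity] * 3, torsL)
            pD = build_chain([topo.L_TO_D_CODE[identity]] * 3, torsD)
            mirror = pL.mirrored()
            xa = pD.coords_array("all-heavy")
            xb = mirror.coords_array("all-heavy")
            assert superpose_kabsch(xa, xb)[2] < 1e-9


class TestTorsionProperties:
    """Property tests over the torsion algebra (derandomized hypothesis)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=-1e4, max_value=1e4, allow_nan=False))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_wrap_angle_range_and_idempotence(self, a):
        w = wrap_angle(a)
        assert -180.0 < w <= 180.0
        assert wrap_angle(w) == w

    @given(st.floats(min_value=-179.0, max_value=179.0),
           st.floats(min_value=-179.0, max_value=179.0),
           st.integers(min_value=0, max_value=2 ** 16))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_build_measure_round_trip_property(self, phi, psi, seed):
        rng = np.random.default_rng(seed)
        tors = [TorsionSet(phi, psi, 180.0, ())] + _random_torsions(rng, 3)
        pose = build_chain(["GLY"] * 4, tors)
        assert abs(wrap_angle(pose.phi(1) - tors[1].phi)) < 1e-6
        assert abs(wrap_angle(pose.psi(0) - psi)) < 1e-6


class TestSuperposition:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        R, t, rmsd = superpose_kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_random_transform(self, rng):
        pts = rng.normal(size=(12, 3)) * 4
        for _ in range(10):
            R = random_rotation(rng)
            t = rng.normal(size=3) * 5
            moved = pts @ R.T + t
            Rh, th, rmsd = superpose_kabsch(moved, pts)
            assert rmsd <= 1e-9
            assert np.linalg.det(Rh) == pytest.approx(1.0)

    def test_mirror_image_not_superposable(self, rng):
        pts = rng.normal(size=(8, 3)) * 3  # generic chiral set
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        _, _, rmsd = superpose_kabsch(mirrored, pts)
        assert rmsd > 0.1

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPoseRmsd:
    def test_self_is_zero(self, rng):
        pose = build_chain(["ALA"] * 5, _random_torsions(rng, 5))
        assert pose_rmsd(pose, pose, "all-heavy") == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_atom_closed_form(self, rng):
        pose = build_chain(["GLY"] * 4, _random_torsions(rng, 4))
        other = pose.copy()
        # displacement without superposition: compare raw coordinate RMSD
        d = 0.25
        other.residues[2].atoms["O"] = other.residues[2].atoms["O"] + [0, 0, d]
        xa = pose.coords_array("all-heavy")
        xb = other.coords_array("all-heavy")
        raw = np.sqrt(((xa - xb) ** 2).sum() / len(xa))
        assert raw == pytest.approx(d / np.sqrt(len(xa)))
        # the superposition-minimized value can only be smaller
        assert pose_rmsd(pose, other, "all-heavy") <= raw + 1e-12

    def test_equals_brute_force_kabsch(self, rng):
        a = build_chain(["ALA"] * 6, _random_torsions(rng, 6))
        b = build_chain(["ALA"] * 6, _random_torsions(rng, 6))
        mine = pose_rmsd(a, b, "backbone-heavy")
        xa = a.coords_array("backbone-heavy")
        xb = b.coords_array("backbone-heavy")
        # independent: direct SVD on centered sets
        xa0 = xa - xa.mean(0)
        xb0 = xb - xb.mean(0)
        U, S, Vt = np.linalg.svd(xa0.T @ xb0)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        rot = Vt.T @ np.diag([1, 1, d]) @ U.T
        ref = np.sqrt((((xa0 @ rot.T) - xb0) ** 2).sum() / len(xa))
        assert mine == pytest.approx(ref, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        a = build_chain(["ALA"] * 5, _random_torsions(rng, 5))
        b = build_chain(["ALA"] * 5, _random_torsions(rng, 5))
        ref = pose_rmsd(a, b, "all-heavy")
        moved = b.transformed(random_rotation(rng), rng.normal(size=3) * 8)
        assert abs(pose_rmsd(a, moved, "all-heavy") - ref) < 1e-9

    def test_selection_mismatch_raises(self, rng):
        a = build_chain(["ALA"] * 4, _random_torsions(rng, 4))
        b = build_chain(["SER"] * 4, _random_torsions(rng, 4))
        with pytest.raises(AtomMappingError):
            pose_rmsd(a, b, "all-heavy")
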