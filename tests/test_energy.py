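"""Energy model: LJ behaviour, H-bond detection, decomposition, invariances."""

import numpy as np
import pytest

from macpep import topology as topo
from macpep.energy import (DEFAULT_PARAMS, PoseAtoms, ScoreParams,
                           count_backbone_hbonds, detect_hbonds,
                           interaction_energy, lj_energy, score)
from macpep.exceptions import ScoringError
from macpep.geometry import (PeptidePose, Residue, TorsionSet, build_chain,
                             random_rotation)
from macpep.pdbio import TargetStructure, structure_from_atoms, structure_from_pose


def _pose(rng, identities=("ALA", "SER", "GLY", "LEU", "ALA")):
    tors = []
    for ident in identities:
        n_chi = topo.get_topology(ident).n_chi
        tors.append(TorsionSet(float(rng.uniform(-170, -40)),
                               float(rng.uniform(-60, 140)), 180.0,
                               tuple(rng.choice([-60.0, 60.0, 180.0])
                                     for _ in range(n_chi))))
    return build_chain(list(identities), tors)


class TestLennardJones:
    def test_minimum_at_contact_distance(self):
        p = DEFAULT_PARAMS
        sigma = np.array([3.2])
        assert lj_energy(sigma, sigma, p)[0] == pytest.approx(-p.lj_epsilon)
        # numerical derivative ~ 0 at the minimum
        h = 1e-6
        d1 = lj_energy(sigma + h, sigma, p)[0]
        d2 = lj_energy(sigma - h, sigma, p)[0]
        assert abs(d1 - d2) / (2 * h) < 1e-6

    def test_strictly_increasing_into_clash(self):
        p = DEFAULT_PARAMS
        sigma = np.full(50, 3.0)
        d = np.linspace(1.0, 0.5, 50) * 3.0
        e = lj_energy(d, sigma, p)
        assert np.all(np.diff(e) > 0)

    def test_finite_at_zero_distance(self):
        assert np.isfinite(lj_energy(np.array([1e-6]), np.array([3.0]),
                                     DEFAULT_PARAMS))[0]


class TestScore:
    def test_total_is_sum_of_terms(self, rng):
        br = score(_pose(rng), None)
        assert br.total == pytest.approx(
            br.steric + br.hbond + br.rama + br.composition)

    def test_pairwise_brute_force_oracle(self, rng):
        """Steric term equals an independently coded double loop with its own
        bonded-exclusion bookkeeping."""
        pose = _pose(rng)
        p = DEFAULT_PARAMS
        br = score(pose, None)
        # independent flattening
        atoms = []
        for i, r in enumerate(pose.residues):
            for name in r.heavy_atom_names():
                atoms.append((i, name, r.atoms[name],
                              topo.VDW_RADII[topo.element_of(name)]))
        # independent bond graph
        import networkx as nx

        g = nx.Graph()
        for i, r in enumerate(pose.residues):
            g.add_edge((i, "N"), (i, "CA"))
            g.add_edge((i, "CA"), (i, "C"))
            g.add_edge((i, "C"), (i, "O"))
            for e in r.topology.sidechain:
                g.add_edge((i, e.parents[2]), (i, e.name))
            for a, b in r.topology.extra_bonds:
                g.add_edge((i, a), (i, b))
            if i + 1 < len(pose):
                g.add_edge((i, "C"), (i + 1, "N"))
        total = 0.0
        for a in range(len(atoms)):
            for b in range(a + 1, len(atoms)):
                ia, na, xa, ra = atoms[a]
                ib, nb, xb, rb = atoms[b]
                try:
                    if nx.shortest_path_length(g, (ia, na), (ib, nb)) <= 3:
                        continue
                except nx.NetworkXNoPath:
                    pass
                d = np.linalg.norm(xa - xb)
                if d < p.lj_cutoff:
                    total += float(lj_energy(np.array([d]),
                                             np.array([ra + rb]), p)[0])
        assert br.steric == pytest.approx(total, abs=1e-9)

    def test_missing_atom_raises_named_error(self, rng):
        pose = _pose(rng)
        del pose.residues[2].atoms["O"]
        with pytest.raises(ScoringError, match="O"):
            score(pose, None)

    def test_rigid_motion_invariance(self, rng, toy_ctx):
        pose = _pose(rng)
        ref = score(pose, None)
        moved = pose.transformed(random_rotation(rng), rng.normal(size=3) * 7)
        got = score(moved, None)
        for term in ("steric", "hbond", "rama", "total"):
            assert abs(getattr(got, term) - getattr(ref, term)) < 1e-9

    def test_mirror_invariance(self, rng):
        """The potential is achiral: a fully mirrored system scores the same."""
        pose = _pose(rng)
        ref = score(pose, None)
        got = score(pose.mirrored(), None)
        assert got.steric == pytest.approx(ref.steric, abs=1e-9)
        assert got.hbond == pytest.approx(ref.hbond, abs=1e-9)
        assert got.total == pytest.approx(ref.total, abs=1e-6)

    def test_interaction_energy_decomposition(self, sampled_solutions, toy_ctx,
                                              toy_target):
        """E(complex) − E(peptide) − E(target) equals the direct cross-term
        computation (the internal terms cancel)."""
        sol = sampled_solutions[0]
        direct = interaction_energy(sol.pose, toy_ctx)
        e_complex = score(sol.pose, toy_ctx).total
        e_pep = score(sol.pose, None).total
        assert direct == pytest.approx(e_complex - e_pep, abs=1e-9)

    def test_composition_term_only_in_design_context(self, rng):
        pose = _pose(rng)
        assert score(pose, None).composition == 0.0
        br = score(pose, None, include_composition=True)
        p = DEFAULT_PARAMS
        expect = sum(p.gly_ala_penalty for r in pose.residues
                     if r.identity in ("GLY", "ALA", "DAL"))
        assert br.composition == pytest.approx(expect)


def _hbond_test_pose(h_to_o: float, angle_deg: float = 160.0):
    """Three residues with a constructed donor(res2)→acceptor(res0) geometry."""
    gly = topo.get_topology("GLY")
    c0 = np.zeros(3)
    o0 = np.array([1.231, 0.0, 0.0])
    res0 = Residue(gly, {"N": np.array([-2.0, 1.0, 0.0]),
                         "CA": np.array([-1.5, 0.0, 0.0]), "C": c0, "O": o0})
    res1 = Residue(gly, {"N": np.array([0.0, 8.0, 0.0]),
                         "CA": np.array([1.0, 8.0, 0.0]),
                         "C": np.array([2.0, 8.0, 0.0]),
                         "O": np.array([2.0, 9.0, 0.0])})
    h = o0 + np.array([h_to_o, 0.0, 0.0])
    ang = np.radians(180.0 - angle_deg)
    nh = 1.01
    n2 = h + nh * np.array([np.cos(ang), np.sin(ang), 0.0])
    res2 = Residue(gly, {"N": n2, "CA": n2 + np.array([0.3, 1.4, 0.0]),
                         "C": n2 + np.array([1.5, 1.9, 0.0]),
                         "O": n2 + np.array([2.2, 2.9, 0.0]), "H": h})
    return PeptidePose([res0, res1, res2])


class TestHBonds:
    def test_isolated_residue_has_none(self):
        pose = build_chain(["ALA"], [TorsionSet(-60, -45, 180, ())])
        assert detect_hbonds(pose) == []
        assert score(pose, None).hbond == 0.0

    def test_constructed_backbone_hbond_detected(self):
        pose = _hbond_test_pose(2.0, 160.0)
        records = [r for r in detect_hbonds(pose)
                   if r.class_ == "intramolecular-backbone"]
        assert len(records) == 1
        rec = records[0]
        assert rec.distance == pytest.approx(2.0, abs=1e-6)
        assert rec.angle == pytest.approx(160.0, abs=1e-6)
        assert count_backbone_hbonds(pose) == 1

    def test_stretched_geometry_rejected(self):
        pose = _hbond_test_pose(3.5, 160.0)
        assert count_backbone_hbonds(pose) == 0

    def test_bent_geometry_rejected(self):
        pose = _hbond_test_pose(2.0, 100.0)
        assert count_backbone_hbonds(pose) == 0

    def test_extended_chain_has_no_backbone_hbonds(self):
        tors = [TorsionSet(180, 180, 180, ()) for _ in range(6)]
        pose = build_chain(["GLY"] * 6, tors)
        assert count_backbone_hbonds(pose) == 0

    def test_count_invariant_under_rigid_motion(self, rng, octacycle):
        pose = octacycle.pose
        ref = count_backbone_hbonds(pose)
        moved = pose.transformed(random_rotation(rng), rng.normal(size=3) * 9)
        assert count_backbone_hbonds(moved) == ref

    def test_class_partition_matches_atom_ownership(self, sampled_solutions,
                                                    toy_ctx):
        """Record classes agree with a brute-force ownership partition."""
        sol = sampled_solutions[0]
        for rec in detect_hbonds(sol.pose, toy_ctx):
            d_owner, a_owner = rec.donor[0], rec.acceptor[0]
            if d_owner == "pose" and a_owner == "pose":
                assert rec.class_.startswith("intramolecular")
                if rec.class_ == "intramolecular-backbone":
                    assert rec.donor[2] == "N" and rec.acceptor[2] == "O"
            else:
                assert rec.class_ == "intermolecular"
                assert {d_owner, a_owner} == {"pose", "target"}


def test_ideal_ring_hbond_count_matches_declared(octacycle):
    assert count_backbone_hbonds(octacycle.pose) == \
        octacycle.declared_backbone_hbonds
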