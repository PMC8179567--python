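"""Kinematic closure: solution correctness against an independent oracle,
closure residuals, determinism, anchor immobility and chirality neutrality."""

import numpy as np
import pytest
from scipy.optimize import root

from macpep import topology as topo
from macpep.closure import KicChain, sample_closed_backbones, solve_closure
from macpep.energy import TargetContext
from macpep.exceptions import AnchorClashError, ParameterError
from macpep.fixtures import make_toy_target
from macpep.geometry import TorsionSet, build_chain, wrap_angle
from macpep.rama import default_bins, sample_phi_psi


def _anchor_stub():
    theta = np.radians(topo.ANGLE_N_CA_C)
    anchor = {"N": np.zeros(3), "CA": np.array([topo.BOND_N_CA, 0.0, 0.0])}
    anchor["C"] = anchor["CA"] + topo.BOND_CA_C * np.array(
        [-np.cos(theta), np.sin(theta), 0.0])
    return anchor


def _random_torsions(n, rng):
    bins = default_bins()
    out = []
    for _ in range(n):
        phi, psi = sample_phi_psi(bins, rng)
        out.append(TorsionSet(phi, psi, 180.0, ()))
    return out


def _scalar_nerf(a, b, c, bond, angle, dihedral):
    """Plain-math internal-to-Cartesian placement (independent of the
    package's numpy implementation)."""
    import math

    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    th = math.radians(angle)
    ch = math.radians(dihedral)
    d0 = -bond * math.cos(th)
    d1 = bond * math.sin(th) * math.cos(ch)
    d2 = bond * math.sin(th) * math.sin(ch)
    return (c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz)


def _scalar_angle(p1, p2, p3):
    import math

    ux, uy, uz = p1[0] - p2[0], p1[1] - p2[1], p1[2] - p2[2]
    vx, vy, vz = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    c = (ux * vx + uy * vy + uz * vz) / (
        math.sqrt(ux * ux + uy * uy + uz * uz)
        * math.sqrt(vx * vx + vy * vy + vz * vz))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _scalar_dihedral(p1, p2, p3, p4):
    import math

    b1 = (p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2])
    b2 = (p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2])
    b3 = (p4[0] - p3[0], p4[1] - p3[1], p4[2] - p3[2])

    def cross(u, v):
        return (u[1] * v[2] - u[2] * v[1], u[2] * v[0] - u[0] * v[2],
                u[0] * v[1] - u[1] * v[0])

    n1, n2 = cross(b1, b2), cross(b2, b3)
    nb2 = math.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    c12 = cross(n1, n2)
    y = (c12[0] * b2[0] + c12[1] * b2[1] + c12[2] * b2[2]) / nb2
    return math.degrees(math.atan2(y, x))


def _closure_residual_system(n, anchor, pivots, torsions):
    """Independent closure equations: the six pivot torsions must make the
    forward-built ring close with ideal bond geometry and reproduce the
    sampled torsions spanning the closing bond."""
    psi_last = torsions[n - 1].psi
    phi_first = torsions[0].phi
    N0 = tuple(anchor["N"])
    CA0 = tuple(anchor["CA"])
    C0 = tuple(anchor["C"])

    def residuals(x):
        phi = [t.phi for t in torsions]
        psi = [t.psi for t in torsions]
        omega = [t.omega for t in torsions]
        for k, p in enumerate(pivots):
            phi[p] = x[2 * k]
            psi[p] = x[2 * k + 1]
        N, CA, C = [N0], [CA0], [C0]
        for i in range(1, n):
            Ni = _scalar_nerf(N[-1], CA[-1], C[-1], topo.BOND_C_N,
                              topo.ANGLE_CA_C_N, psi[i - 1])
            CAi = _scalar_nerf(CA[-1], C[-1], Ni, topo.BOND_N_CA,
                               topo.ANGLE_C_N_CA, omega[i])
            Ci = _scalar_nerf(C[-1], Ni, CAi, topo.BOND_CA_C,
                              topo.ANGLE_N_CA_C, phi[i])
            N.append(Ni)
            CA.append(CAi)
            C.append(Ci)
        import math

        dx = (C[-1][0] - N0[0], C[-1][1] - N0[1], C[-1][2] - N0[2])
        bond = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        return np.array([
            bond - topo.BOND_C_N,
            _scalar_angle(CA[-1], C[-1], N0) - topo.ANGLE_CA_C_N,
            _scalar_angle(C[-1], N0, CA0) - topo.ANGLE_C_N_CA,
            wrap_angle(_scalar_dihedral(CA[-1], C[-1], N0, CA0) - 180.0),
            wrap_angle(_scalar_dihedral(N[-1], CA[-1], C[-1], N0) - psi_last),
            wrap_angle(_scalar_dihedral(C[-1], N0, CA0, C0) - phi_first),
        ])

    return residuals


def _oracle_solutions(n, anchor, pivots, torsions, n_starts=1500, seed=0):
    """Dense multistart Newton search over the six pivot torsions."""
    rng = np.random.default_rng(seed)
    residuals = _closure_residual_system(n, anchor, pivots, torsions)
    found = []
    for _ in range(n_starts):
        x0 = rng.uniform(-180, 180, size=6)
        sol = root(residuals, x0, method="hybr", tol=1e-12)
        if not sol.success or np.max(np.abs(residuals(sol.x))) > 1e-8:
            continue
        x = np.array([wrap_angle(v) for v in sol.x])
        if not any(np.max(np.abs((x - f + 180) % 360 - 180)) < 0.05
                   for f in found):
            found.append(x)
    return found


class TestSolveClosure:
    def test_self_consistency_recovers_pivots(self, rng):
        anchor = _anchor_stub()
        pivots = (2, 4, 7)
        for _ in range(30):
            tors = _random_torsions(9, rng)
            sols = solve_closure(KicChain(["GLY"] * 9, anchor, 0, pivots), tors)
            if not sols:
                continue
            ref = sols[0]
            pose = ref.pose
            tors2 = [TorsionSet(pose.phi(i), pose.psi(i), pose.omega(i), ())
                     for i in range(9)]
            sols2 = solve_closure(KicChain(["GLY"] * 9, anchor, 0, pivots), tors2)
            target = np.array(ref.pivot_torsions)
            best = min(np.max(np.abs((np.array(s.pivot_torsions) - target + 180)
                                     % 360 - 180)) for s in sols2)
            assert best < 1e-4
            return
        pytest.fail("no closure solution found in 30 attempts")

    @pytest.mark.parametrize("n", [7, 8])
    def test_matches_multistart_oracle(self, n):
        """Solution count and torsion values agree with an independent
        numeric search of the full closure system (one instance per ring
        size here; the full-scale version runs in the acceptance suite)."""
        anchor = _anchor_stub()
        pivots = (1, 3, 5)
        rng = np.random.default_rng(100 + n)
        checked = 0
        attempts = 0
        while checked < 1 and attempts < 40:
            attempts += 1
            tors = _random_torsions(n, rng)
            sols = solve_closure(KicChain(["GLY"] * n, anchor, 0, pivots),
                                 tors, grid=2880)
            if not sols:
                continue
            oracle = _oracle_solutions(n, anchor, pivots, tors, seed=n)
            assert len(oracle) == len(sols), (n, attempts)
            mine = [np.array(s.pivot_torsions) for s in sols]
            for ox in oracle:
                err = min(np.max(np.abs((m - ox + 180) % 360 - 180))
                          for m in mine)
                assert err < 1e-3
            # every analytic solution satisfies the independent system
            system = _closure_residual_system(n, anchor, pivots, tors)
            for m in mine:
                assert np.max(np.abs(system(m))) < 1e-6
            checked += 1
        assert checked == 1

    def test_at_most_16_solutions(self, rng):
        anchor = _anchor_stub()
        for _ in range(40):
            tors = _random_torsions(8, rng)
            sols = solve_closure(KicChain(["GLY"] * 8, anchor, 0, (1, 4, 6)), tors)
            assert len(sols) <= 16

    def test_closing_bond_geometry(self, sampled_solutions):
        assert sampled_solutions
        for sol in sampled_solutions:
            res = sol.pose.closure_residual()
            assert abs(res["bond_length"] - 1.329) <= 0.01
            assert res["angle_error"] <= 1.0

    def test_mirror_chirality_neutrality(self, rng):
        """Mirroring the anchor and negating all sampled torsions yields the
        mirrored solution set."""
        anchor = _anchor_stub()
        m = np.array([1.0, 1.0, -1.0])
        anchor_m = {k: v * m for k, v in anchor.items()}
        found = 0
        for _ in range(20):
            tors = _random_torsions(8, rng)
            tors_m = [TorsionSet(-t.phi, -t.psi, -t.omega, ()) for t in tors]
            chain = KicChain(["GLY"] * 8, anchor, 0, (2, 4, 6))
            chain_m = KicChain(["GLY"] * 8, anchor_m, 0, (2, 4, 6))
            sols = solve_closure(chain, tors)
            sols_m = solve_closure(chain_m, tors_m)
            assert len(sols) == len(sols_m)
            if not sols:
                continue
            found += 1
            for s in sols:
                mirrored = s.pose.coords_array("backbone-heavy") * m
                best = min(np.max(np.abs(
                    mirrored - sm.pose.coords_array("backbone-heavy")))
                    for sm in sols_m)
                assert best < 1e-6
        assert found >= 3


class TestSampling:
    def test_zero_attempts_empty(self, anchored_pose, toy_ctx):
        assert sample_closed_backbones(anchored_pose, toy_ctx, 0, seed=1) == []

    def test_seed_determinism(self, anchored_pose, toy_ctx):
        a = sample_closed_backbones(anchored_pose, toy_ctx, 40, seed=5)
        b = sample_closed_backbones(anchored_pose, toy_ctx, 40, seed=5)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.pivot_torsions == y.pivot_torsions
            assert np.array_equal(x.pose.coords_array("all-heavy"),
                                  y.pose.coords_array("all-heavy"))

    @pytest.mark.parametrize("ring_size", [8, 9, 10])
    def test_supported_ring_sizes(self, trp_anchor, toy_ctx, ring_size):
        from macpep.hotspot import extend_polygly

        n_nterm = (ring_size - 1) // 2
        pose = extend_polygly(trp_anchor, n_nterm, ring_size - 1 - n_nterm)
        sols = sample_closed_backbones(pose, toy_ctx, 120, seed=2)
        assert sols, f"no closed solutions for ring size {ring_size}"
        for s in sols:
            assert len(s.pose) == ring_size
            assert s.pose.cyclic

    def test_anchor_immobile_across_samples(self, anchored_pose, sampled_solutions):
        a = anchored_pose.anchor_index
        ref = anchored_pose.residues[a]
        for sol in sampled_solutions:
            res = sol.pose.residues[a]
            for name, xyz in ref.atoms.items():
                assert np.array_equal(res.atoms[name], xyz), name

    def test_ring_size_out_of_range(self, trp_anchor, toy_ctx):
        from macpep.hotspot import extend_polygly

        pose = extend_polygly(trp_anchor, 3, 3)  # 7-mer is fine
        sample_closed_backbones(pose, toy_ctx, 1, seed=1)
        with pytest.raises(ParameterError):
            bad = extend_polygly(trp_anchor, 6, 6)  # 13-mer
            sample_closed_backbones(bad, toy_ctx, 1, seed=1)

    def test_anchor_clash_error(self, toy_target):
        structure, site = toy_target
        from macpep.hotspot import HotspotAnchor, extend_polygly

        # drop the anchor straight into the sheet
        inside = structure.coords.mean(axis=0)
        theta = np.radians(topo.ANGLE_N_CA_C)
        atoms = {"N": inside, "CA": inside + [topo.BOND_N_CA, 0, 0]}
        atoms["C"] = atoms["CA"] + topo.BOND_CA_C * np.array(
            [-np.cos(theta), np.sin(theta), 0.0])
        anchor = HotspotAnchor("GLY", "achiral", atoms, (), "rotamer-scan")
        pose = extend_polygly(anchor, 4, 4)
        with pytest.raises(AnchorClashError):
            sample_closed_backbones(pose, TargetContext(structure), 5, seed=1)
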