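"""Generalized kinematic closure for anchored peptide macrocycles.

The ring is cut conceptually at the fixed anchor residue; three pivot
residues (six backbone torsions) are solved so that the chain — built with
ideal bond lengths/angles, trans amides and the sampled non-pivot torsions —
closes head-to-tail.  The problem reduces to the classic triaxial form: the
three pivot Cα atoms span a rigid triangle; each inter-pivot chain segment is
a rigid body hinging about a triangle edge, and the prefix/suffix chains fix
the first and last pivot Cα in space.  The N-Cα-C angle conditions at the
three pivots give two cone equations (solved in closed form per branch) and
one scalar residual in the triangle hinge angle, whose roots are located on a
dense grid and polished by Brent's method.  The four cone-branch
combinations × up to four hinge roots reproduce the ≤ 16 real solutions of
the degree-16 closure polynomial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import topology as topo
from .energy import DEFAULT_PARAMS, ScoreParams, as_context, has_clash, score
from .exceptions import AnchorClashError, GeometryError, ParameterError
from .geometry import (PeptidePose, TorsionSet, build_chain, measure_dihedral,
                       place_atom, wrap_angle)
from .rama import bins_for_chirality, default_bins, sample_phi_psi

log = logging.getLogger(__name__)

_THETA = np.radians(topo.ANGLE_N_CA_C)  # pivot joint angle


@dataclass
class KicChain:
    """Ring description handed to the closure solver."""

    topologies: list
    anchor_atoms: dict            # full anchor residue atom map (N/CA/C fixed)
    anchor_index: int
    pivots: tuple[int, int, int]  # distinct, non-anchor residue indices

    def __post_init__(self):
        self.topologies = [topo.get_topology(t) if isinstance(t, str) else t
                           for t in self.topologies]
        n = len(self.topologies)
        a = self.anchor_index
        piv = tuple(sorted(set(int(p) % n for p in self.pivots),
                           key=lambda i: (i - a) % n))
        if len(piv) != 3 or a in piv:
            raise ParameterError("pivots must be three distinct non-anchor residues")
        self.pivots = piv

    @property
    def n(self) -> int:
        return len(self.topologies)


@dataclass
class ClosureSolution:
    """One closed-ring backbone with closure diagnostics."""

    pivot_torsions: tuple  # (φ,ψ) at the three pivots, traversal order
    pose: PeptidePose
    residual: dict
    energy: object = None  # EnergyBreakdown, filled by the sampler

    @property
    def total_energy(self) -> float:
        return self.energy.total if self.energy is not None else float("nan")


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector in closure geometry")
    return v / n


def _bootstrap_pair(origin, direction_bond, angle_deg, bond1, bond2):
    """Seed two atoms: B at origin + bond1*x̂, C placed at the given angle in
    the xy-plane."""
    theta = np.radians(angle_deg)
    b = origin + np.array([bond1, 0.0, 0.0])
    c = b + bond2 * np.array([-np.cos(theta), np.sin(theta), 0.0])
    return b, c


class _RingWalker:
    """Forward/backward ideal-geometry walks around the ring."""

    def __init__(self, chain: KicChain, torsions):
        self.chain = chain
        self.t = torsions
        self.n = chain.n

    def forward_prefix(self):
        """Anchor → first pivot; returns atoms dict keyed (i, name)."""
        c = self.chain
        atoms = {(c.anchor_index, k): np.asarray(c.anchor_atoms[k], float)
                 for k in ("N", "CA", "C")}
        i = c.anchor_index
        while True:
            j = (i + 1) % self.n
            N = place_atom(atoms[(i, "N")], atoms[(i, "CA")], atoms[(i, "C")],
                           topo.BOND_C_N, topo.ANGLE_CA_C_N, self.t[i].psi)
            CA = place_atom(atoms[(i, "CA")], atoms[(i, "C")], N,
                            topo.BOND_N_CA, topo.ANGLE_C_N_CA, self.t[j].omega)
            atoms[(j, "N")] = N
            atoms[(j, "CA")] = CA
            if j == c.pivots[0]:
                return atoms
            atoms[(j, "C")] = place_atom(atoms[(i, "C")], N, CA,
                                         topo.BOND_CA_C, topo.ANGLE_N_CA_C,
                                         self.t[j].phi)
            i = j

    def backward_suffix(self):
        """Anchor → last pivot (walking backwards)."""
        c = self.chain
        atoms = {(c.anchor_index, k): np.asarray(c.anchor_atoms[k], float)
                 for k in ("N", "CA", "C")}
        j = c.anchor_index
        while True:
            i = (j - 1) % self.n
            C = place_atom(atoms[(j, "C")], atoms[(j, "CA")], atoms[(j, "N")],
                           topo.BOND_C_N, topo.ANGLE_C_N_CA, self.t[j].phi)
            CA = place_atom(atoms[(j, "CA")], atoms[(j, "N")], C,
                            topo.BOND_CA_C, topo.ANGLE_CA_C_N, self.t[j].omega)
            atoms[(i, "C")] = C
            atoms[(i, "CA")] = CA
            if i == c.pivots[2]:
                return atoms
            atoms[(i, "N")] = place_atom(atoms[(j, "N")], C, CA,
                                         topo.BOND_N_CA, topo.ANGLE_N_CA_C,
                                         self.t[i].psi)
            j = i

    def segment(self, p_from: int, p_to: int):
        """Rigid inter-pivot segment built in a local frame.

        Contains CA/C of ``p_from``, full residues strictly between, and
        N/CA of ``p_to``.
        """
        atoms: dict[tuple[int, str], np.ndarray] = {}
        i = p_from
        j = (i + 1) % self.n
        # seed: C_pfrom at origin, N_{i+1} along x, CA_{i+1} in xy-plane
        atoms[(i, "C")] = np.zeros(3)
        Nj, CAj = _bootstrap_pair(atoms[(i, "C")], None, topo.ANGLE_C_N_CA,
                                  topo.BOND_C_N, topo.BOND_N_CA)
        atoms[(j, "N")] = Nj
        atoms[(j, "CA")] = CAj
        # attach CA_pfrom via the fixed ω of residue j
        atoms[(i, "CA")] = place_atom(CAj, Nj, atoms[(i, "C")],
                                      topo.BOND_CA_C, topo.ANGLE_CA_C_N,
                                      self.t[j].omega)
        while j != p_to:
            atoms[(j, "C")] = place_atom(atoms[(i, "C")], atoms[(j, "N")],
                                         atoms[(j, "CA")], topo.BOND_CA_C,
                                         topo.ANGLE_N_CA_C, self.t[j].phi)
            i, j = j, (j + 1) % self.n
            N = place_atom(atoms[(i, "N")], atoms[(i, "CA")], atoms[(i, "C")],
                           topo.BOND_C_N, topo.ANGLE_CA_C_N, self.t[i].psi)
            CA = place_atom(atoms[(i, "CA")], atoms[(i, "C")], N,
                            topo.BOND_N_CA, topo.ANGLE_C_N_CA, self.t[j].omega)
            atoms[(j, "N")] = N
            atoms[(j, "CA")] = CA
        return atoms


def _local_frame(z, ref_vec):
    """Orthonormal (m, n, z) with m along ref_vec's component ⊥ z."""
    m = ref_vec - np.dot(ref_vec, z) * z
    nm = np.linalg.norm(m)
    if nm < 1e-10:
        raise GeometryError("degenerate azimuth reference")
    m /= nm
    return m, np.cross(z, m)


def solve_closure(chain: KicChain, sampled_torsions, grid: int = 1440,
                  bond_tol: float = 0.01, angle_tol: float = 1.0,
                  chis=None) -> list[ClosureSolution]:
    """All real pivot-torsion solutions closing the ring.

    ``sampled_torsions`` is a sequence of :class:`TorsionSet` for every
    residue (pivot φ/ψ entries are ignored and replaced by the solver).
    Geometrically infeasible samples yield an empty list.
    """
    n = chain.n
    if n < 6:
        raise ParameterError("ring size must be at least 6 residues")
    t = list(sampled_torsions)
    if len(t) != n:
        raise ParameterError("need one TorsionSet per residue")
    p1, p2, p3 = chain.pivots
    walker = _RingWalker(chain, t)
    try:
        prefix = walker.forward_prefix()
        suffix = walker.backward_suffix()
        seg1 = walker.segment(p1, p2)
        seg2 = walker.segment(p2, p3)
    except GeometryError:
        return []

    CA1w = prefix[(p1, "CA")]
    N1w = prefix[(p1, "N")]
    CA3w = suffix[(p3, "CA")]
    C3w = suffix[(p3, "C")]
    r1_in = _unit(N1w - CA1w)
    r3_out = _unit(C3w - CA3w)

    # segment internals
    CA1l, C1l = seg1[(p1, "CA")], seg1[(p1, "C")]
    CA2l_1, N2l = seg1[(p2, "CA")], seg1[(p2, "N")]
    z1l = _unit(CA2l_1 - CA1l)
    v1 = _unit(C1l - CA1l)
    cos_g1 = float(np.dot(v1, z1l))
    sin_g1 = float(np.sqrt(max(0.0, 1.0 - cos_g1 ** 2)))
    try:
        m1l, n1l = _local_frame(z1l, v1)
    except GeometryError:
        return []
    u2 = _unit(N2l - CA2l_1)
    q1 = np.array([np.dot(u2, m1l), np.dot(u2, n1l), np.dot(u2, z1l)])

    CA2l_2, C2l = seg2[(p2, "CA")], seg2[(p2, "C")]
    CA3l, N3l = seg2[(p3, "CA")], seg2[(p3, "N")]
    z2l = _unit(CA3l - CA2l_2)
    v3 = _unit(N3l - CA3l)
    qz3 = float(np.dot(v3, z2l))
    qp3 = float(np.sqrt(max(0.0, 1.0 - qz3 ** 2)))
    try:
        m2l, n2l = _local_frame(z2l, v3)
    except GeometryError:
        return []
    c2 = _unit(C2l - CA2l_2)
    q2 = np.array([np.dot(c2, m2l), np.dot(c2, n2l), np.dot(c2, z2l)])

    d12 = float(np.linalg.norm(CA2l_1 - CA1l))
    d23 = float(np.linalg.norm(CA3l - CA2l_2))
    d13 = float(np.linalg.norm(CA3w - CA1w))
    if d13 < 1e-6 or d12 + d23 <= d13 or abs(d12 - d23) >= d13:
        return []
    cos_beta = (d12 ** 2 + d13 ** 2 - d23 ** 2) / (2.0 * d12 * d13)
    if not -1.0 < cos_beta < 1.0:
        return []
    u = _unit(CA3w - CA1w)
    rho = d12 * float(np.sqrt(1.0 - cos_beta ** 2))
    if rho < 1e-6:
        return []
    foot = CA1w + d12 * cos_beta * u
    # deterministic basis perpendicular to u
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(u)))] = 1.0
    e1 = _unit(np.cross(u, ref))
    e2 = np.cross(u, e1)

    cos_t = np.cos(_THETA)

    def geometry(sigma):
        """Per-σ quantities; σ may be an array."""
        sigma = np.atleast_1d(np.asarray(sigma, float))
        CA2 = foot[None, :] + rho * (np.cos(sigma)[:, None] * e1[None, :]
                                     + np.sin(sigma)[:, None] * e2[None, :])
        w1 = CA2 - CA1w
        w1 /= np.linalg.norm(w1, axis=1, keepdims=True)
        w2 = CA3w[None, :] - CA2
        w2 /= np.linalg.norm(w2, axis=1, keepdims=True)
        # frames: m ⟂ axis, seeded from the fixed triangle base direction u
        m1 = u[None, :] - (w1 @ u)[:, None] * w1
        m1 /= np.linalg.norm(m1, axis=1, keepdims=True)
        n1 = np.cross(w1, m1)
        m2 = u[None, :] - (w2 @ u)[:, None] * w2
        m2 /= np.linalg.norm(m2, axis=1, keepdims=True)
        n2 = np.cross(w2, m2)
        return CA2, w1, m1, n1, w2, m2, n2

    def cone_roots(a, b, c):
        """Solve a + b cosx + c sinx = cos_t: returns (phi0, delta, valid).

        ``delta`` uses the clipped arccos so the branch residual remains a
        continuous function of σ across cone-feasibility boundaries — roots
        lying just inside a boundary are then found by ordinary bracketing,
        and any spurious root from the clipped (infeasible) region fails the
        rebuilt-pose closure-residual check downstream.
        """
        r = np.hypot(b, c)
        with np.errstate(invalid="ignore", divide="ignore"):
            h = (cos_t - a) / r
        valid = (r > 1e-12) & (np.abs(h) <= 1.0 + 1e-9)
        delta = np.arccos(np.clip(h, -1.0, 1.0))
        return np.arctan2(c, b), delta, valid

    def branch_values(sigma, s1, s2):
        CA2, w1, m1, n1, w2, m2, n2 = geometry(sigma)
        a1 = cos_g1 * (w1 @ r1_in)
        b1 = sin_g1 * (m1 @ r1_in)
        c1 = sin_g1 * (n1 @ r1_in)
        phi0_1, delta_1, ok1 = cone_roots(a1, b1, c1)
        alpha = phi0_1 + s1 * delta_1
        a3 = qz3 * (w2 @ r3_out)
        b3 = qp3 * (m2 @ r3_out)
        c3 = qp3 * (n2 @ r3_out)
        phi0_3, delta_3, ok3 = cone_roots(a3, b3, c3)
        beta = phi0_3 + s2 * delta_3
        ca, sa = np.cos(alpha), np.sin(alpha)
        m_a = ca[:, None] * m1 + sa[:, None] * n1
        n_a = ca[:, None] * n1 - sa[:, None] * m1
        r2_in = q1[0] * m_a + q1[1] * n_a + q1[2] * w1
        cb, sb = np.cos(beta), np.sin(beta)
        m_b = cb[:, None] * m2 + sb[:, None] * n2
        n_b = cb[:, None] * n2 - sb[:, None] * m2
        r2_out = q2[0] * m_b + q2[1] * n_b + q2[2] * w2
        g = np.einsum("ij,ij->i", r2_in, r2_out) - cos_t
        return g, ok1 & ok3, alpha, beta

    sigmas = np.linspace(-np.pi, np.pi, grid, endpoint=False)
    roots = []
    for s1 in (+1.0, -1.0):
        for s2 in (+1.0, -1.0):
            # bracket on the clipped residual (continuous across feasibility
            # boundaries); infeasible roots are weeded out by the closure
            # residual of the rebuilt pose
            g, _, _, _ = branch_values(sigmas, s1, s2)
            for k in range(grid):
                k2 = (k + 1) % grid
                gk, gk2 = g[k], g[k2]
                if not (np.isfinite(gk) and np.isfinite(gk2)):
                    continue
                if gk == 0.0:
                    roots.append((float(sigmas[k]), s1, s2))
                elif gk * gk2 < 0.0:
                    lo = sigmas[k]
                    hi = sigmas[k2] if k2 != 0 else sigmas[k] + (sigmas[1] - sigmas[0])

                    def f(x, s1=s1, s2=s2):
                        val, _, _, _ = branch_values(x, s1, s2)
                        return float(val[0])

                    try:
                        roots.append((float(brentq(f, lo, hi, xtol=1e-13)), s1, s2))
                    except (ValueError, RuntimeError):
                        continue

    solutions = []
    seen: list[np.ndarray] = []
    for sigma, s1, s2 in roots:
        _, ok, alpha_arr, beta_arr = branch_values(sigma, s1, s2)
        if not ok[0]:
            continue
        alpha = float(alpha_arr[0])
        beta = float(beta_arr[0])
        CA2, w1, m1, n1, w2, m2, n2 = geometry(sigma)
        CA2, w1, m1, n1, w2, m2, n2 = (x[0] for x in (CA2, w1, m1, n1, w2, m2, n2))
        # rigid placement of the two segments
        Bw1 = np.column_stack([np.cos(alpha) * m1 + np.sin(alpha) * n1,
                               np.cos(alpha) * n1 - np.sin(alpha) * m1, w1])
        Bl1 = np.column_stack([m1l, n1l, z1l])
        M1 = Bw1 @ Bl1.T
        Bw2 = np.column_stack([np.cos(beta) * m2 + np.sin(beta) * n2,
                               np.cos(beta) * n2 - np.sin(beta) * m2, w2])
        Bl2 = np.column_stack([m2l, n2l, z2l])
        M2 = Bw2 @ Bl2.T

        world: dict[tuple[int, str], np.ndarray] = {}
        world.update(prefix)
        for key, xyz in seg1.items():
            world[key] = CA1w + M1 @ (xyz - CA1l)
        for key, xyz in seg2.items():
            world[key] = CA2 + M2 @ (xyz - CA2l_2)
        world.update(suffix)

        def dih(i1, a1n, i2, a2n, i3, a3n, i4, a4n):
            return measure_dihedral(world[(i1, a1n)], world[(i2, a2n)],
                                    world[(i3, a3n)], world[(i4, a4n)])

        try:
            piv_t = []
            for p in (p1, p2, p3):
                pm = (p - 1) % n
                pp = (p + 1) % n
                phi = dih(pm, "C", p, "N", p, "CA", p, "C")
                psi = dih(p, "N", p, "CA", p, "C", pp, "N")
                piv_t.extend([phi, psi])
        except (KeyError, GeometryError):
            continue
        vec = np.array(piv_t)
        if any(np.max(np.abs((vec - s + 180.0) % 360.0 - 180.0)) < 1e-3
               for s in seen):
            continue
        full = [TorsionSet(ts.phi, ts.psi, ts.omega, ts.chis) for ts in t]
        for k_p, p in enumerate((p1, p2, p3)):
            full[p] = TorsionSet(piv_t[2 * k_p], piv_t[2 * k_p + 1],
                                 t[p].omega, t[p].chis)
        pose = build_chain(chain.topologies, full,
                           anchor={k: chain.anchor_atoms[k] for k in ("N", "CA", "C")},
                           anchor_index=chain.anchor_index, cyclic=True,
                           anchor_all_atoms=chain.anchor_atoms)
        res = pose.closure_residual()
        if res["bond_error"] > bond_tol or res["angle_error"] > angle_tol \
                or res["omega_error"] > 5.0:
            continue
        seen.append(vec)
        solutions.append(ClosureSolution(tuple(piv_t), pose, res))
    return solutions


# ---------------------------------------------------------------------------
# Monte-Carlo backbone sampling against a target
# ---------------------------------------------------------------------------


def sample_torsions_for(topology, bins, rng) -> tuple[float, float]:
    """Draw (φ, ψ) for one residue, respecting chirality and Pro φ limits."""
    if topology.chirality == "achiral":
        usable = bins
    else:
        usable = bins_for_chirality(bins, topology.chirality) or bins
    phi, psi = sample_phi_psi(usable, rng)
    if topology.phi_range is not None:
        lo, hi = topology.phi_range
        phi = float(rng.uniform(lo, hi))
    return phi, psi


def _attempt_rng(seed: int, attempt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(attempt)]))


def _sample_ring(topologies, anchor_atoms, anchor_index, n_attempts, bins,
                 seed, target_ctx=None, params: ScoreParams = DEFAULT_PARAMS,
                 score_against_target: bool = True, fixed_pivots=None,
                 grid: int = 720, stats: dict | None = None,
                 anchor_torsions: TorsionSet | None = None,
                 per_position_bins=None, max_solutions=None):
    """Shared sampling loop behind target-templated and free sampling."""
    n = len(topologies)
    tops = [topo.get_topology(t) if isinstance(t, str) else t for t in topologies]
    free = [i for i in range(n) if i != anchor_index]
    counters = {"attempts": 0, "closed": 0, "clash_rejected": 0, "kept": 0}
    out = []
    for attempt in range(n_attempts):
        rng = _attempt_rng(seed, attempt)
        counters["attempts"] += 1
        if fixed_pivots is not None:
            pivots = tuple(fixed_pivots)
        else:
            pivots = tuple(int(x) for x in rng.choice(free, size=3, replace=False))
        torsions = []
        for i, t in enumerate(tops):
            if i == anchor_index and anchor_torsions is not None:
                torsions.append(anchor_torsions)
                continue
            use_bins = per_position_bins[i] if per_position_bins is not None else bins
            phi, psi = sample_torsions_for(t, use_bins, rng)
            torsions.append(TorsionSet(phi, psi, 180.0, ()))
        try:
            chain = KicChain(tops, anchor_atoms, anchor_index, pivots)
        except ParameterError:
            continue
        sols = solve_closure(chain, torsions, grid=grid)
        counters["closed"] += len(sols)
        for sol in sols:
            if target_ctx is not None:
                pa_entries = [(i, name) for i, name in
                              sol.pose.atom_entries("all-heavy")
                              if i != anchor_index]
                coords = np.array([sol.pose.residues[i].atoms[nm]
                                   for i, nm in pa_entries])
                radii = np.array([topo.VDW_RADII[topo.element_of(nm)]
                                  for _, nm in pa_entries])
                if has_clash(coords, radii, target_ctx, frac=params.clash_frac):
                    counters["clash_rejected"] += 1
                    continue
            if score_against_target and target_ctx is not None:
                sol.energy = score(sol.pose, target_ctx, params)
            elif score_against_target:
                sol.energy = score(sol.pose, None, params)
            counters["kept"] += 1
            out.append(sol)
        if max_solutions is not None and len(out) >= max_solutions:
            break
    if stats is not None:
        stats.update(counters)
    log.info("closure sampling: %s", counters)
    return out


def sample_closed_backbones(anchored_pose: PeptidePose, target, n_attempts: int,
                            bins=None, seed: int = 0,
                            params: ScoreParams = DEFAULT_PARAMS,
                            fixed_pivots=None, grid: int = 720,
                            stats: dict | None = None):
    """Sample closed, clash-screened macrocycle backbones around the anchor.

    The anchor residue of ``anchored_pose`` keeps its coordinates bit-exactly;
    every returned pose is head-to-tail closed within tolerance and free of
    hard-sphere clashes with the target.  Fully reproducible under ``seed``
    (per-attempt child seeds, so execution order is irrelevant).
    """
    n = len(anchored_pose)
    if not 7 <= n <= 12:
        raise ParameterError("ring size must be within [7, 12]")
    if n_attempts <= 0:
        return []
    anchor_index = anchored_pose.anchor_index
    if anchor_index is None:
        raise ParameterError("anchored pose must mark an anchor residue")
    if bins is None:
        bins = default_bins()
    ctx = as_context(target)
    anchor_res = anchored_pose.residues[anchor_index]
    if ctx is not None:
        names = anchor_res.heavy_atom_names()
        coords = np.array([anchor_res.atoms[nm] for nm in names])
        radii = np.array([topo.VDW_RADII[topo.element_of(nm)] for nm in names])
        if has_clash(coords, radii, ctx, frac=params.clash_frac):
            raise AnchorClashError("anchor residue overlaps the target")
    return _sample_ring([r.topology for r in anchored_pose.residues],
                        dict(anchor_res.atoms), anchor_index, n_attempts, bins,
                        seed, target_ctx=ctx, params=params,
                        fixed_pivots=fixed_pivots, grid=grid, stats=stats)
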