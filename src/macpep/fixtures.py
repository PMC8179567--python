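"""Deterministic synthetic test inputs.

Everything here is a geometric stand-in built from ideal geometry so that
the full pipeline, the oracles and the acceptance checks run without any
download: a rigid β-sheet slab with a designated hotspot site (emulating a
large, flat sheet-dominated binding surface), a pre-docked hotspot residue
complex, and exactly closed ideal macrocycles with known torsions and
hydrogen-bond counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import topology as topo
from .closure import KicChain, _sample_ring, solve_closure
from .energy import count_backbone_hbonds, score
from .exceptions import FixtureGenerationError, ParameterError
from .geometry import PeptidePose, TorsionSet, build_chain, pose_rmsd
from .hotspot import HotspotAnchor, rotamer_scan_place
from .pdbio import TargetStructure, structure_from_atoms, structure_from_pose
from .rama import default_bins

_STRAND_PHI = -120.0
_STRAND_PSI = 130.0


def make_toy_target(seed: int = 0, n_strands: int = 3, strand_len: int = 10,
                    jitter: float = 0.03):
    """A small rigid β-sheet slab with a shallow surface groove.

    Returns ``(TargetStructure, site)`` where ``site`` holds the designated
    hotspot Cα position (above the sheet face) and the outward surface
    normal.  Same seed → byte-identical structure.
    """
    rng = np.random.default_rng(seed)
    tors = [TorsionSet(_STRAND_PHI, _STRAND_PSI, 180.0, ()) for _ in range(strand_len)]
    base = build_chain(["ALA"] * strand_len, tors)
    rows = []
    resseq = 0
    flip = np.diag([-1.0, 1.0, -1.0])  # 180° about y: antiparallel partner
    for s in range(n_strands):
        shift = np.array([0.0, 4.8 * s, 0.0])
        for i, r in enumerate(base.residues):
            resseq += 1
            for name in ("N", "CA", "C", "O", "CB"):
                xyz = r.atoms[name]
                if s % 2 == 1:
                    xyz = flip @ xyz + np.array([33.0, 0.0, 0.0])
                xyz = xyz + shift + rng.normal(0.0, jitter, 3)
                rows.append(("A", resseq, "", "ALA", name, topo.element_of(name),
                             xyz, 1.0, 0.0))
        resseq += 10  # numbering gap between strands
    structure = structure_from_atoms(rows, source=f"toy-target(seed={seed})")
    # hotspot site: above the middle of the sheet face
    coords = structure.coords
    center = coords.mean(axis=0)
    top = coords[:, 2].max()
    site = {
        "site": np.array([center[0], center[1], top + 4.6]),
        "normal": np.array([0.0, 0.0, 1.0]),
    }
    return structure, site


def make_toy_complex(seed: int = 0, identity: str = "TYR"):
    """Toy target plus a pre-docked hotspot residue as partner chain B.

    Returns ``(TargetStructure complex, HotspotAnchor placed, target-only
    structure)``; useful for testing extraction against a known source.
    """
    target, site = make_toy_target(seed)
    anchor, _ = rotamer_scan_place(target, identity, site["site"], site["normal"])
    from .geometry import Residue

    pose = PeptidePose([Residue(topo.get_topology(identity), anchor.atoms)])
    partner = structure_from_pose(pose, chain_id="B", start_resseq=1)
    rows = []
    for s in (target, partner):
        for i in range(s.n_atoms):
            rows.append((str(s.chain_ids[i]), int(s.resseqs[i]), str(s.icodes[i]),
                         str(s.resnames[i]), str(s.names[i]), str(s.elements[i]),
                         s.coords[i].copy(), float(s.occupancies[i]),
                         float(s.b_factors[i])))
    complex_structure = structure_from_atoms(rows, source="toy-complex")
    return complex_structure, anchor, target


@dataclass
class IdealMacrocycle:
    """A generated exactly closed ring with its declared properties."""

    pose: PeptidePose
    chirality_pattern: str
    declared_backbone_hbonds: int
    energy: float


def _pattern_string(n: int, pattern: str) -> str:
    if pattern == "alternating":
        return ("LD" * n)[:n]
    if pattern == "all-L":
        return "L" * n
    if set(pattern) <= {"L", "D"} and len(pattern) == n:
        return pattern
    raise ParameterError(f"unknown chirality pattern {pattern!r} for n={n}")


_CACHE: dict[tuple, IdealMacrocycle] = {}


def _anchor_stub():
    theta = np.radians(topo.ANGLE_N_CA_C)
    anchor = {"N": np.zeros(3), "CA": np.array([topo.BOND_N_CA, 0.0, 0.0])}
    anchor["C"] = anchor["CA"] + topo.BOND_CA_C * np.array(
        [-np.cos(theta), np.sin(theta), 0.0])
    return anchor


def _refine_ring(pose: PeptidePose, anchor_atoms, iters: int = 8,
                 step: float = 4.0, keep_hbonds: int = 0) -> PeptidePose:
    """Coordinate descent on the free backbone torsions with re-closure,
    driving the ring into a local energy minimum while never dropping below
    ``keep_hbonds`` backbone hydrogen bonds."""
    n = len(pose)
    # alternate pivot triples between rounds so every torsion is optimized
    # directly at some point (pivot torsions are solved, not stepped)
    pivot_sets = [tuple(sorted({1, n // 2, n - 1})),
                  tuple(sorted({2, (n // 2 + 1) % n or 1, n - 2}))]
    pivot_sets = [p for p in pivot_sets if len(p) == 3 and 0 not in p]
    cur_pose = pose
    cur_e = score(pose, None).total
    tops = [r.topology for r in pose.residues]
    for round_ in range(iters):
        pivots = pivot_sets[round_ % len(pivot_sets)]
        free = [i for i in range(n) if i not in pivots]
        tors = [TorsionSet(cur_pose.phi(i), cur_pose.psi(i),
                           cur_pose.omega(i), ()) for i in range(n)]
        improved = False
        for i in free:
            for attr in ("phi", "psi"):
                for d in (step, -step):
                    trial = [TorsionSet(t.phi, t.psi, t.omega, t.chis)
                             for t in tors]
                    setattr(trial[i], attr, getattr(trial[i], attr) + d)
                    sols = solve_closure(
                        KicChain(tops, anchor_atoms, 0, pivots), trial,
                        grid=720)
                    if not sols:
                        continue
                    near = min(sols, key=lambda s: pose_rmsd(s.pose, cur_pose))
                    if pose_rmsd(near.pose, cur_pose) > 1.0:
                        continue
                    e = score(near.pose, None).total
                    if e < cur_e - 1e-6 and \
                            count_backbone_hbonds(near.pose) >= keep_hbonds:
                        cur_e, cur_pose, tors = e, near.pose, trial
                        improved = True
        step *= 0.7
        if not improved:
            step *= 0.5
            if step < 0.2:
                break
    return cur_pose


def _polish_ring(pose: PeptidePose, anchor_atoms, maxfev: int = 600) -> PeptidePose:
    """Simplex minimization over all free torsions (with re-closure),
    converging the ring onto its local basin floor."""
    from scipy.optimize import minimize

    n = len(pose)
    pivots = tuple(sorted({1, n // 2, n - 1}))
    free = [i for i in range(n) if i not in pivots]
    tops = [r.topology for r in pose.residues]
    best = {"pose": pose, "e": score(pose, None).total}

    def objective(x):
        tors = [TorsionSet(pose.phi(i), pose.psi(i), pose.omega(i), ())
                for i in range(n)]
        for k, i in enumerate(free):
            tors[i] = TorsionSet(x[2 * k], x[2 * k + 1], tors[i].omega, ())
        sols = solve_closure(KicChain(tops, anchor_atoms, 0, pivots), tors,
                             grid=360)
        if not sols:
            return 50.0
        near = min(sols, key=lambda s: pose_rmsd(s.pose, pose))
        if pose_rmsd(near.pose, pose) > 1.5:
            return 50.0
        e = score(near.pose, None).total
        if e < best["e"]:
            best["pose"], best["e"] = near.pose, e
        return e

    x0 = []
    for i in free:
        x0 += [pose.phi(i), pose.psi(i)]
    minimize(objective, np.array(x0), method="Nelder-Mead",
             options={"maxfev": maxfev, "xatol": 0.02, "fatol": 1e-5})
    return best["pose"]


def make_ideal_macrocycle(n_residues: int, pattern: str = "alternating",
                          seed: int = 0, attempts: int = 2500,
                          min_hbonds: int = 2,
                          refine: bool = True) -> IdealMacrocycle:
    """An exactly closed head-to-tail macrocycle with a requested chirality
    pattern (Ala residues of matching hand).

    Closure samples are drawn with chirality-matched Ramachandran bins and
    filtered to conformers realizing the pattern.  The lowest-energy
    candidate at each backbone hydrogen-bond level ≥ ``min_hbonds`` is
    locally refined (torsion coordinate descent with re-closure, preserving
    its hydrogen bonds) and the deepest refined minimum wins — the fixture
    therefore represents a rigid, hydrogen-bond-stabilized ring with a
    declared bond count sitting at a true local energy minimum.
    """
    if not 6 <= n_residues <= 12:
        raise ParameterError("ideal macrocycles support 6-12 residues")
    key = (n_residues, pattern, seed, attempts, min_hbonds, refine)
    if key in _CACHE:
        cached = _CACHE[key]
        return IdealMacrocycle(cached.pose.copy(), cached.chirality_pattern,
                               cached.declared_backbone_hbonds, cached.energy)
    pat = _pattern_string(n_residues, pattern)
    identities = ["ALA" if c == "L" else "DAL" for c in pat]
    anchor = _anchor_stub()
    sols = _sample_ring(identities, anchor, 0, attempts, default_bins(), seed,
                        target_ctx=None, score_against_target=True)
    # the closure solver leaves pivot torsions unconstrained: keep only
    # conformers whose realized φ signs match the requested pattern
    def pattern_ok(pose):
        from .design import position_chiralities

        p = pose.copy()
        p.anchor_mask = [False] * len(p)
        return "".join(position_chiralities(p)) == pat

    sols = [s for s in sols if pattern_ok(s.pose)]
    if not sols:
        raise FixtureGenerationError(
            f"no closed conformer for n={n_residues}, pattern={pattern}")
    by_level: dict[int, object] = {}
    for s in sols:
        h = count_backbone_hbonds(s.pose)
        if h >= min_hbonds and (h not in by_level
                                or s.energy.total < by_level[h].energy.total):
            by_level[h] = s
    # multi-start refinement: per-H-bond-level winners (preserving their
    # level) plus the overall lowest-energy conformers (free descent); the
    # deepest refined minimum that keeps the pattern and ≥ min_hbonds wins
    starts = [(s, h) for h, s in sorted(by_level.items())]
    if refine:
        for s in sorted(sols, key=lambda x: x.energy.total)[:6]:
            if all(s is not t for t, _ in starts):
                starts.append((s, 0))
    if not starts:
        best = max(sols, key=lambda s: (count_backbone_hbonds(s.pose),
                                        -s.energy.total))
        starts = [(best, 0)]
    candidates = []
    for s, keep in starts:
        cand = s.pose
        if refine:
            refined = _refine_ring(s.pose, anchor, keep_hbonds=keep)
            if pattern_ok(refined):
                cand = refined
        candidates.append((score(cand, None).total, len(candidates), cand))
    if refine:
        # simplex-polish the most promising minima onto their basin floors
        candidates.sort(key=lambda x: x[0])
        polished = []
        for e, k, cand in candidates[:3]:
            p = _polish_ring(cand, anchor)
            if pattern_ok(p):
                polished.append((score(p, None).total, -1 - k, p))
        candidates.extend(polished)
    pose, pose_e = None, None
    fallback, fallback_e = None, None
    for e, _, cand in sorted(candidates, key=lambda x: x[0]):
        hb = count_backbone_hbonds(cand)
        if hb >= min_hbonds and (pose_e is None or e < pose_e):
            pose, pose_e = cand, e
        if fallback_e is None or e < fallback_e:
            fallback, fallback_e = cand, e
    if pose is None:
        pose = fallback
    hb = count_backbone_hbonds(pose)
    e = score(pose, None).total
    out = IdealMacrocycle(pose, pat, hb, e)
    _CACHE[key] = IdealMacrocycle(pose.copy(), pat, hb, e)
    return out
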