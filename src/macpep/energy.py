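"""Simplified decomposable energy function and hydrogen-bond detection.

The potential is deliberately small and fully documented: a 6-12
Lennard-Jones steric term with a linear ramp below a fraction of the contact
distance (finite for any clash), a geometric hydrogen-bond bonus, a
Ramachandran bin-weight term, and a sequence-composition term (Gly/Ala
penalty, Pro bonus) that only applies during design.  It is achiral and
rigid-motion invariant; there is no solvation or electrostatics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import rama as rama_mod
from . import topology as topo
from .exceptions import ScoringError
from .geometry import PeptidePose, measure_angle
from .pdbio import TargetStructure


@dataclass(frozen=True)
class ScoreParams:
    """Weights and geometric criteria of the energy function."""

    lj_epsilon: float = 0.05      # well depth per heavy-atom pair
    lj_cutoff: float = 6.0        # Å
    lj_ramp_frac: float = 0.6     # linear ramp below this fraction of contact
    hbond_energy: float = -0.5    # per hydrogen bond at ideal geometry
    hbond_dist: float = 2.5       # H···A cutoff, Å
    hbond_heavy_dist: float = 3.3  # D···A cutoff when no H is present, Å
    hbond_angle: float = 120.0    # D-H···A minimum, degrees
    rama_weight: float = 1.0
    rama_floor: float = 0.01      # weight floor for -log
    gly_ala_penalty: float = 1.0
    pro_bonus: float = 1.0
    clash_frac: float = 0.6       # hard-sphere rejection threshold
    polar_contact_bonus: float = -0.3  # design-move reward per polar contact
    polar_contact_dist: float = 3.2    # Å


DEFAULT_PARAMS = ScoreParams()


@dataclass
class EnergyBreakdown:
    """Per-term energies; ``total`` is always their sum."""

    steric: float
    hbond: float
    rama: float
    composition: float
    total: float
    context: str  # "peptide-alone" | "peptide+target"

    @classmethod
    def from_terms(cls, steric, hbond, rama, composition, context):
        return cls(steric, hbond, rama, composition,
                   steric + hbond + rama + composition, context)


@dataclass(frozen=True)
class HBondRecord:
    donor: tuple        # ("pose", res_idx, atom) or ("target", atom_idx, atom)
    acceptor: tuple
    distance: float     # H···A (or D···A for heavy-only donors), Å
    angle: float        # D-H···A (or antecedent-D···A), degrees
    class_: str         # intramolecular-backbone | intramolecular-sidechain | intermolecular
    heavy_criterion: bool = False  # True when no explicit H was available


# donor heavy atom -> antecedent atom, per identity (L names; D map via parent)
_SC_DONORS = {
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "LYS": {"NZ": "CE"}, "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"}, "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CE1"}, "TRP": {"NE1": "CD1"},
}
_SC_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}


def _parent_identity(name3: str) -> str:
    return topo.D_CODES.get(name3, name3)


# ---------------------------------------------------------------------------
# Pose flattening and bonded-pair exclusions
# ---------------------------------------------------------------------------


class PoseAtoms:
    """Flat heavy-atom view of a pose with a ≤3-bond exclusion matrix."""

    def __init__(self, pose: PeptidePose):
        self.pose = pose
        entries = pose.atom_entries("all-heavy")
        self.entries = entries
        self.index = {e: k for k, e in enumerate(entries)}
        self.coords = np.array([pose.residues[i].atoms[n] for i, n in entries])
        self.res_idx = np.array([i for i, _ in entries])
        self.names = [n for _, n in entries]
        self.elements = [topo.element_of(n) for n in self.names]
        self.radii = np.array([topo.VDW_RADII[e] for e in self.elements])
        self.is_backbone = np.array([n in topo.BACKBONE_HEAVY for n in self.names])
        self.excluded = self._exclusions()

    def _bonds(self):
        bonds = []
        pose = self.pose
        for i, r in enumerate(pose.residues):
            def add(a, b, i=i):
                ka = self.index.get((i, a))
                kb = self.index.get((i, b))
                if ka is not None and kb is not None:
                    bonds.append((ka, kb))
            add("N", "CA"); add("CA", "C"); add("C", "O")
            for entry in r.topology.sidechain:
                add(entry.parents[2], entry.name)
            for a, b in r.topology.extra_bonds:
                add(a, b)
            j = i + 1
            if j < len(pose) or pose.cyclic:
                j %= len(pose)
                kc = self.index.get((i, "C"))
                kn = self.index.get((j, "N"))
                if kc is not None and kn is not None:
                    bonds.append((kc, kn))
        return bonds

    def _exclusions(self) -> np.ndarray:
        n = len(self.entries)
        adj = [[] for _ in range(n)]
        for a, b in self._bonds():
            adj[a].append(b)
            adj[b].append(a)
        excl = np.zeros((n, n), dtype=bool)
        for start in range(n):
            frontier = {start}
            seen = {start}
            for _ in range(3):  # up to 1-4 pairs excluded
                frontier = {nb for x in frontier for nb in adj[x]} - seen
                seen |= frontier
            excl[start, list(seen)] = True
        return excl

    def bond_distance_leq3(self, ka: int, kb: int) -> bool:
        return bool(self.excluded[ka, kb])


class TargetContext:
    """Cached KD-tree and per-atom annotations for a target structure."""

    def __init__(self, structure: TargetStructure):
        self.structure = structure
        heavy = np.array([e != "H" for e in structure.elements])
        self.heavy_idx = np.nonzero(heavy)[0]
        self.coords = structure.coords[self.heavy_idx]
        self.radii = structure.radii[self.heavy_idx]
        self.names = [str(structure.names[i]) for i in self.heavy_idx]
        self.resnames = [str(structure.resnames[i]) for i in self.heavy_idx]
        self.res_key = [(str(structure.chain_ids[i]), int(structure.resseqs[i]),
                         str(structure.icodes[i])) for i in self.heavy_idx]
        self.tree = cKDTree(self.coords)
        self._residue_atom: dict[tuple, dict[str, int]] = {}
        for k, key in enumerate(self.res_key):
            self._residue_atom.setdefault(key, {})[self.names[k]] = k

    def atom_in_residue(self, key, name):
        return self._residue_atom.get(key, {}).get(name)


def as_context(target) -> "TargetContext | None":
    if target is None or isinstance(target, TargetContext):
        return target
    return TargetContext(target)


# ---------------------------------------------------------------------------
# Lennard-Jones with linear ramp
# ---------------------------------------------------------------------------


def lj_energy(d: np.ndarray, sigma: np.ndarray, params: ScoreParams) -> np.ndarray:
    """6-12 LJ with minimum −ε at d = σ and a linear ramp below
    ``lj_ramp_frac``·σ (keeps clash energies finite)."""
    d = np.asarray(d, float)
    sigma = np.asarray(sigma, float)
    eps = params.lj_epsilon
    d0 = params.lj_ramp_frac * sigma
    dd = np.maximum(d, d0)
    x6 = (sigma / dd) ** 6
    e = eps * (x6 * x6 - 2.0 * x6)
    x06 = (1.0 / params.lj_ramp_frac) ** 6
    slope = (12.0 * eps / d0) * (x06 * x06 - x06)
    return np.where(d < d0, e + slope * (d0 - d), e)


def _pairwise_steric(pa: PoseAtoms, params: ScoreParams) -> float:
    n = len(pa.coords)
    if n < 2:
        return 0.0
    diff = pa.coords[:, None, :] - pa.coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    sigma = pa.radii[:, None] + pa.radii[None, :]
    mask = np.triu(np.ones((n, n), bool), 1) & ~pa.excluded & (d < params.lj_cutoff)
    if not mask.any():
        return 0.0
    return float(lj_energy(d[mask], sigma[mask], params).sum())


def _cross_steric(pa: PoseAtoms, ctx: TargetContext, params: ScoreParams) -> float:
    total = 0.0
    neighbor_lists = ctx.tree.query_ball_point(pa.coords, params.lj_cutoff)
    for k, nbrs in enumerate(neighbor_lists):
        if not nbrs:
            continue
        nbrs = np.asarray(nbrs)
        d = np.linalg.norm(ctx.coords[nbrs] - pa.coords[k], axis=1)
        sigma = pa.radii[k] + ctx.radii[nbrs]
        total += float(lj_energy(d, sigma, params).sum())
    return total


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def _falloff(dist, cutoff, angle, params: ScoreParams) -> float:
    fd = np.clip((cutoff - dist) / 0.5, 0.0, 1.0)
    fa = np.clip((angle - params.hbond_angle) / 40.0, 0.0, 1.0)
    return float(fd * fa)


def _pose_donors(pose: PeptidePose, pa: PoseAtoms):
    """Yield (res_idx, heavy_name, H coords or None, heavy coords, antecedent)."""
    for i, r in enumerate(pose.residues):
        if r.topology.has_amide_h and "H" in r.atoms and "N" in r.atoms:
            yield (i, "N", r.atoms["H"], r.atoms["N"], r.atoms["CA"], True)
        table = _SC_DONORS.get(_parent_identity(r.identity), {})
        for name, ante in table.items():
            if name in r.atoms and ante in r.atoms:
                yield (i, name, None, r.atoms[name], r.atoms[ante], False)


def _pose_acceptors(pose: PeptidePose):
    for i, r in enumerate(pose.residues):
        if "O" in r.atoms:
            yield (i, "O", r.atoms["O"], True)
        for name in _SC_ACCEPTORS.get(_parent_identity(r.identity), ()):
            if name in r.atoms:
                yield (i, name, r.atoms[name], False)


def _target_donors(ctx: TargetContext):
    for k, name in enumerate(ctx.names):
        rid = _parent_identity(ctx.resnames[k])
        if name == "N" and rid != "PRO":
            ante = ctx.atom_in_residue(ctx.res_key[k], "CA")
            yield (k, name, ctx.coords[k],
                   ctx.coords[ante] if ante is not None else None)
        elif name in _SC_DONORS.get(rid, {}):
            ante = ctx.atom_in_residue(ctx.res_key[k], _SC_DONORS[rid][name])
            yield (k, name, ctx.coords[k],
                   ctx.coords[ante] if ante is not None else None)


def _target_acceptors(ctx: TargetContext):
    for k, name in enumerate(ctx.names):
        rid = _parent_identity(ctx.resnames[k])
        if name == "O" or name in _SC_ACCEPTORS.get(rid, ()):
            yield (k, name, ctx.coords[k])


def detect_hbonds(pose: PeptidePose, target=None,
                  params: ScoreParams = DEFAULT_PARAMS) -> list[HBondRecord]:
    """All donor/acceptor pairs meeting the geometric criteria.

    Backbone amide donors use the explicit H (H···A ≤ ``hbond_dist`` and
    D-H···A ≥ ``hbond_angle``); donors without a built hydrogen (side chains,
    target atoms) fall back to a heavy-atom criterion
    (D···A ≤ ``hbond_heavy_dist``, antecedent-D···A ≥ 90°).
    """
    ctx = as_context(target)
    pa = PoseAtoms(pose)
    records: list[HBondRecord] = []

    pose_donors = list(_pose_donors(pose, pa))
    pose_acceptors = list(_pose_acceptors(pose))

    def try_pair(di, dname, h, dxyz, ante, has_h, ai, aname, axyz, inter,
                 a_is_bb, d_is_bb):
        if not inter and di == ai:
            return
        if not inter:
            kd = pa.index.get((di, dname))
            ka = pa.index.get((ai, aname))
            if kd is not None and ka is not None and pa.bond_distance_leq3(kd, ka):
                return
        if has_h:
            dist = float(np.linalg.norm(axyz - h))
            if dist > params.hbond_dist:
                return
            ang = measure_angle(dxyz, h, axyz)
            if ang < params.hbond_angle:
                return
        else:
            dist = float(np.linalg.norm(axyz - dxyz))
            if dist > params.hbond_heavy_dist:
                return
            ang = measure_angle(ante, dxyz, axyz) if ante is not None else 180.0
            if ang < 90.0:
                return
        if inter:
            cls = "intermolecular"
        elif a_is_bb and d_is_bb:
            cls = "intramolecular-backbone"
        else:
            cls = "intramolecular-sidechain"
        records.append(HBondRecord(("pose", di, dname), ("pose", ai, aname),
                                   dist, ang, cls, heavy_criterion=not has_h))

    # pose donor -> pose acceptor
    for di, dname, h, dxyz, ante, has_h in pose_donors:
        d_is_bb = dname == "N"
        for ai, aname, axyz, a_is_bb in pose_acceptors:
            try_pair(di, dname, h, dxyz, ante, has_h, ai, aname, axyz,
                     False, a_is_bb, d_is_bb)

    if ctx is not None:
        t_acceptors = list(_target_acceptors(ctx))
        t_donors = list(_target_donors(ctx))
        # pose donor -> target acceptor
        for di, dname, h, dxyz, ante, has_h in pose_donors:
            ref = h if has_h else dxyz
            for ak, aname, axyz in t_acceptors:
                if np.linalg.norm(axyz - ref) > params.hbond_heavy_dist + 1.0:
                    continue
                if has_h:
                    dist = float(np.linalg.norm(axyz - h))
                    if dist > params.hbond_dist:
                        continue
                    ang = measure_angle(dxyz, h, axyz)
                    if ang < params.hbond_angle:
                        continue
                else:
                    dist = float(np.linalg.norm(axyz - dxyz))
                    if dist > params.hbond_heavy_dist:
                        continue
                    ang = measure_angle(ante, dxyz, axyz) if ante is not None else 180.0
                    if ang < 90.0:
                        continue
                records.append(HBondRecord(("pose", di, dname),
                                           ("target", int(ak), aname),
                                           dist, ang, "intermolecular",
                                           heavy_criterion=not has_h))
        # target donor -> pose acceptor (heavy criterion)
        for dk, dname, dxyz, ante in t_donors:
            for ai, aname, axyz, _ in pose_acceptors:
                dist = float(np.linalg.norm(axyz - dxyz))
                if dist > params.hbond_heavy_dist:
                    continue
                ang = measure_angle(ante, dxyz, axyz) if ante is not None else 180.0
                if ang < 90.0:
                    continue
                records.append(HBondRecord(("target", int(dk), dname),
                                           ("pose", ai, aname),
                                           dist, ang, "intermolecular",
                                           heavy_criterion=True))
    return records


def count_backbone_hbonds(pose: PeptidePose,
                          params: ScoreParams = DEFAULT_PARAMS) -> int:
    """Number of intramolecular backbone–backbone hydrogen bonds."""
    return sum(1 for r in detect_hbonds(pose, None, params)
               if r.class_ == "intramolecular-backbone")


def _hbond_term(records, params: ScoreParams, classes) -> float:
    total = 0.0
    for r in records:
        if r.class_ not in classes:
            continue
        if r.heavy_criterion:
            # angle was measured at the donor heavy atom (≥ 90 by selection);
            # use a unit angular factor
            total += params.hbond_energy * np.clip(
                (params.hbond_heavy_dist - r.distance) / 0.5, 0.0, 1.0)
        else:
            total += params.hbond_energy * _falloff(
                r.distance, params.hbond_dist, r.angle, params)
    return total


# ---------------------------------------------------------------------------
# Full score
# ---------------------------------------------------------------------------


def _rama_term(pose: PeptidePose, params: ScoreParams, bins) -> float:
    total = 0.0
    for i in range(len(pose)):
        phi = pose.phi(i)
        psi = pose.psi(i)
        if phi is None or psi is None:
            continue
        w = rama_mod.bin_weight(phi, psi, bins)
        total += -params.rama_weight * np.log(max(w, params.rama_floor))
    return float(total)


def composition_energy(identities, params: ScoreParams = DEFAULT_PARAMS) -> float:
    """Gly/Ala penalty and Pro bonus over a sequence."""
    e = 0.0
    for name in identities:
        parent = _parent_identity(name)
        if parent in ("GLY", "ALA"):
            e += params.gly_ala_penalty
        elif parent == "PRO":
            e -= params.pro_bonus
    return e


def score(pose: PeptidePose, target=None, params: ScoreParams = DEFAULT_PARAMS,
          include_composition: bool = False, bins=None) -> EnergyBreakdown:
    """Deterministic decomposable energy of a pose, optionally with target.

    Raises :class:`ScoringError` when backbone heavy atoms are missing.
    """
    for i, r in enumerate(pose.residues):
        for name in ("N", "CA", "C", "O"):
            if name not in r.atoms:
                raise ScoringError(f"residue {i} ({r.identity}) missing atom {name}")
    ctx = as_context(target)
    pa = PoseAtoms(pose)
    steric = _pairwise_steric(pa, params)
    if ctx is not None:
        steric += _cross_steric(pa, ctx, params)
    records = detect_hbonds(pose, ctx, params)
    classes = {"intramolecular-backbone", "intramolecular-sidechain"}
    if ctx is not None:
        classes.add("intermolecular")
    hbond = _hbond_term(records, params, classes)
    rama = _rama_term(pose, params, bins)
    comp = composition_energy(pose.sequence3(), params) if include_composition else 0.0
    context = "peptide+target" if ctx is not None else "peptide-alone"
    return EnergyBreakdown.from_terms(steric, hbond, rama, comp, context)


def interaction_energy(pose: PeptidePose, target,
                       params: ScoreParams = DEFAULT_PARAMS) -> float:
    """E(complex) − E(peptide) − E(target): cross steric + intermolecular
    hydrogen bonds (the decomposable terms cancel exactly)."""
    ctx = as_context(target)
    if ctx is None:
        raise ScoringError("interaction energy requires a target")
    pa = PoseAtoms(pose)
    cross = _cross_steric(pa, ctx, params)
    records = detect_hbonds(pose, ctx, params)
    hb = _hbond_term(records, params, {"intermolecular"})
    return float(cross + hb)


def has_clash(coords_a, radii_a, ctx_or_coords, radii_b=None,
              frac: float = 0.6) -> bool:
    """Hard-sphere test: any pair closer than ``frac``·(r_i + r_j)."""
    if isinstance(ctx_or_coords, TargetContext):
        tree = ctx_or_coords.tree
        cb = ctx_or_coords.coords
        rb = ctx_or_coords.radii
    else:
        cb = np.asarray(ctx_or_coords)
        rb = np.asarray(radii_b)
        tree = cKDTree(cb)
    rmax = float(np.max(rb)) if len(rb) else 0.0
    for xyz, ra in zip(np.asarray(coords_a), np.asarray(radii_a)):
        for j in tree.query_ball_point(xyz, frac * (ra + rmax)):
            if np.linalg.norm(cb[j] - xyz) < frac * (ra + rb[j]):
                return True
    return False
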