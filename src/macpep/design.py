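"""Chirality-constrained Monte-Carlo sequence/rotamer design.

Positions with backbone φ < 0 may receive L-amino acids, positions with
φ > 0 D-amino acids (Gly is allowed on either side); the anchor keeps its
identity and coordinates.  Simulated annealing over (identity, rotamer)
moves uses a cheap local objective (steric + polar-contact reward +
composition); the returned record is always re-scored with the full energy
function and full interface metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from . import topology as topo
from .energy import (DEFAULT_PARAMS, ScoreParams, as_context, lj_energy, score)
from .exceptions import ConfigurationError, RankingError
from .geometry import PeptidePose, TorsionSet, build_sidechain
from .interface import InterfaceReport, interface_report
from .rama import assign_chirality
from .rotamers import rotamer_set

log = logging.getLogger(__name__)


def position_chiralities(pose: PeptidePose) -> list[str]:
    """Per-position chirality by the φ-sign rule (anchor reports its own)."""
    out = []
    for i, r in enumerate(pose.residues):
        if pose.anchor_mask[i]:
            out.append(r.chirality if r.chirality != "achiral" else "L")
            continue
        phi = pose.phi(i)
        out.append(assign_chirality(phi if phi is not None else -60.0))
    return out


@dataclass(frozen=True)
class DesignPalette:
    """Allowed identities and composition incentives.

    ``identities`` lists parent L 3-letter codes; positions assigned D by
    the φ-sign rule use the mirrored codes automatically, and Gly is allowed
    at either kind of position.
    """

    identities: tuple[str, ...] = tuple(sorted(
        set(topo.ONE_LETTER) - {"GLY", "CYS", "MET"}))
    allow_gly: bool = True

    def codes_for(self, chirality: str) -> tuple[str, ...]:
        if not self.identities and not self.allow_gly:
            raise ConfigurationError("empty design palette")
        codes = []
        for name in self.identities:
            codes.append(name if chirality == "L" else topo.L_TO_D_CODE[name])
        if self.allow_gly:
            codes.append("GLY")
        return tuple(codes)


@dataclass(frozen=True)
class MCSchedule:
    """Simulated-annealing schedule: geometric temperature ladder."""

    moves: int = 5000
    t_start: float = 3.0
    t_end: float = 0.3
    stages: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.moves <= 0 or self.stages <= 0:
            raise ConfigurationError("moves and stages must be positive")
        if not self.t_start > self.t_end > 0:
            raise ConfigurationError("temperatures must be strictly decreasing")

    def temperatures(self) -> np.ndarray:
        return np.geomspace(self.t_start, self.t_end, self.stages)


@dataclass
class DesignRecord:
    """A designed sequence on a sampled backbone, with ranking metrics."""

    pose: PeptidePose
    sequence: list[str]
    chis: list[tuple[float, ...]]
    energy: object                 # EnergyBreakdown
    report: InterfaceReport | None
    ring_size: int
    design_id: str = ""
    best_energy_trace: list = field(default_factory=list)
    source_energy: float = float("nan")       # E of the sampled backbone
    source_backbone_hbonds: int = -1          # backbone H-bonds pre-design

    def sequence_string(self) -> str:
        return "".join(topo.get_topology(n).one_letter for n in self.sequence)


def metropolis_accept(delta: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion; at T → 0 only strictly improving moves pass."""
    if delta <= 0:
        return True
    if temperature <= 1e-12:
        return False
    return bool(rng.random() < math.exp(-delta / temperature))


@lru_cache(maxsize=64)
def _own_exclusions(identity: str) -> dict[str, frozenset[str]]:
    """Own-residue atoms within 3 bonds of each side-chain atom."""
    t = topo.get_topology(identity)
    adj: dict[str, set[str]] = {n: set() for n in ("N", "CA", "C", "O")}
    for a, b in (("N", "CA"), ("CA", "C"), ("C", "O")):
        adj[a].add(b)
        adj[b].add(a)
    for e in t.sidechain:
        adj.setdefault(e.name, set())
        adj.setdefault(e.parents[2], set())
        adj[e.name].add(e.parents[2])
        adj[e.parents[2]].add(e.name)
    for a, b in t.extra_bonds:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for name in [e.name for e in t.sidechain]:
        seen = {name}
        frontier = {name}
        for _ in range(3):
            frontier = {nb for x in frontier for nb in adj[x]} - seen
            seen |= frontier
        out[name] = frozenset(seen)
    return out


class _DesignContext:
    """Static environment for fast per-move energy deltas."""

    def __init__(self, pose: PeptidePose, target_ctx, params: ScoreParams):
        self.pose = pose
        self.params = params
        self.target = target_ctx
        entries = []
        for i, r in enumerate(pose.residues):
            for name in ("N", "CA", "C", "O"):
                entries.append((i, name))
        self.bb_entries = entries
        self.bb_coords = np.array([pose.residues[i].atoms[n] for i, n in entries])
        self.bb_radii = np.array([topo.VDW_RADII[topo.element_of(n)]
                                  for _, n in entries])
        self.bb_polar = np.array([n in ("N", "O") for _, n in entries])
        self.bb_tree = cKDTree(self.bb_coords)
        if target_ctx is not None:
            self.t_polar = np.array([nm[0] in ("N", "O") for nm in target_ctx.names])

    def sidechain_atoms(self, i: int, identity: str, chis) -> dict[str, np.ndarray]:
        t = topo.get_topology(identity)
        base = {k: self.pose.residues[i].atoms[k] for k in ("N", "CA", "C", "O")}
        build_sidechain(base, t, tuple(chis))
        return {e.name: base[e.name] for e in t.sidechain}

    def local_energy(self, i: int, identity: str, chis,
                     other_sidechains: dict[int, dict[str, np.ndarray]]) -> float:
        """Steric + polar-contact energy of position i's side chain against
        target, backbone and the other positions' current side chains,
        plus the composition term."""
        p = self.params
        parent = topo.D_CODES.get(identity, identity)
        e = 0.0
        if parent in ("GLY", "ALA"):
            e += p.gly_ala_penalty
        elif parent == "PRO":
            e -= p.pro_bonus
        if topo.get_topology(identity).n_chi == 0 and parent in ("GLY",):
            return e
        sc = self.sidechain_atoms(i, identity, chis)
        excl = _own_exclusions(identity)
        n_pose = len(self.pose)
        # flatten other side chains once
        oc, orad, opol = [], [], []
        for j, atoms in other_sidechains.items():
            if j == i:
                continue
            for name, xyz in atoms.items():
                oc.append(xyz)
                el = topo.element_of(name)
                orad.append(topo.VDW_RADII[el])
                opol.append(el in ("N", "O"))
        oc = np.array(oc) if oc else np.zeros((0, 3))
        orad = np.array(orad)
        opol = np.array(opol, bool)
        for name, xyz in sc.items():
            el = topo.element_of(name)
            ra = topo.VDW_RADII[el]
            polar = el in ("N", "O")
            # vs target
            if self.target is not None:
                nbrs = self.target.tree.query_ball_point(xyz, p.lj_cutoff)
                if nbrs:
                    nbrs = np.asarray(nbrs)
                    d = np.linalg.norm(self.target.coords[nbrs] - xyz, axis=1)
                    e += float(lj_energy(d, ra + self.target.radii[nbrs], p).sum())
                    if polar:
                        close = d <= p.polar_contact_dist
                        e += p.polar_contact_bonus * int(
                            np.count_nonzero(self.t_polar[nbrs][close]))
            # vs pose backbone (with bonded exclusions)
            nbrs = self.bb_tree.query_ball_point(xyz, p.lj_cutoff)
            for k in nbrs:
                j, bname = self.bb_entries[k]
                if j == i and bname in excl.get(name, ()):
                    continue
                if name == "CB":
                    prev_c = (j == (i - 1) % n_pose and bname == "C"
                              and (self.pose.cyclic or j == i - 1))
                    next_n = (j == (i + 1) % n_pose and bname == "N"
                              and (self.pose.cyclic or j == i + 1))
                    if prev_c or next_n:
                        continue
                d = float(np.linalg.norm(self.bb_coords[k] - xyz))
                e += float(lj_energy(d, ra + self.bb_radii[k], p))
                if polar and self.bb_polar[k] and d <= p.polar_contact_dist \
                        and j != i:
                    e += p.polar_contact_bonus
            # vs other side chains
            if len(oc):
                d = np.linalg.norm(oc - xyz, axis=1)
                mask = d < p.lj_cutoff
                if mask.any():
                    e += float(lj_energy(d[mask], ra + orad[mask], p).sum())
                    if polar:
                        e += p.polar_contact_bonus * int(np.count_nonzero(
                            opol[mask] & (d[mask] <= p.polar_contact_dist)))
        return e


def design(pose: PeptidePose, target, palette: DesignPalette | None = None,
           library=None, schedule: MCSchedule | None = None,
           params: ScoreParams = DEFAULT_PARAMS, bins=None,
           compute_report: bool = True, refine: bool = True) -> DesignRecord:
    """Metropolis MC over (identity, rotamer) moves at non-anchor positions.

    Reproducible under ``schedule.seed``; the best-so-far energy trace is
    monotone non-increasing.  The anchor residue's identity and coordinates
    are never touched.
    """
    palette = palette or DesignPalette()
    schedule = schedule or MCSchedule()
    ctx = as_context(target)
    pose = pose.copy()
    rng = np.random.default_rng(schedule.seed)
    chir = position_chiralities(pose)
    n = len(pose)
    anchor = pose.anchor_index

    allowed: list[tuple[str, ...]] = []
    for i in range(n):
        if i == anchor:
            allowed.append((pose.residues[i].identity,))
        else:
            allowed.append(palette.codes_for(chir[i]))
        if not allowed[-1]:
            raise ConfigurationError(f"no identity allowed at position {i}")
    lib = library or {code: rotamer_set(code)
                      for codes in allowed for code in codes}

    dctx = _DesignContext(pose, ctx, params)
    identities, chis, sidechains = [], [], {}
    for i in range(n):
        if i == anchor:
            r = pose.residues[i]
            identities.append(r.identity)
            chis.append(tuple(pose.chis(i)))
            sidechains[i] = {e.name: r.atoms[e.name]
                             for e in r.topology.sidechain if e.name in r.atoms}
        else:
            ident = allowed[i][0]
            identities.append(ident)
            chis.append(tuple((lib.get(ident) or [()])[0]))
            sidechains[i] = (dctx.sidechain_atoms(i, ident, chis[i])
                             if topo.get_topology(ident).sidechain else {})

    locals_ = [dctx.local_energy(i, identities[i], chis[i], sidechains)
               if i != anchor else 0.0 for i in range(n)]
    e_curr = float(sum(locals_))
    best = (e_curr, list(identities), list(chis))
    trace = [e_curr]

    designable = [i for i in range(n) if i != anchor]
    temps = schedule.temperatures()
    per_stage = max(1, schedule.moves // schedule.stages)
    for T in temps:
        for _ in range(per_stage):
            i = int(rng.choice(designable))
            code = allowed[i][int(rng.integers(len(allowed[i])))]
            rots = lib.get(code) or [()]
            new_chis = rots[int(rng.integers(len(rots)))]
            old_e = locals_[i]
            new_sc = dctx.sidechain_atoms(i, code, new_chis) \
                if topo.get_topology(code).sidechain else {}
            # energy with the move applied
            saved_id, saved_chis, saved_sc = identities[i], chis[i], sidechains[i]
            identities[i], chis[i], sidechains[i] = code, tuple(new_chis), new_sc
            new_e = dctx.local_energy(i, code, new_chis, sidechains)
            delta = new_e - old_e
            if metropolis_accept(delta, float(T), rng):
                locals_[i] = new_e
                e_curr += delta
                if e_curr < best[0]:
                    best = (e_curr, list(identities), list(chis))
            else:
                identities[i], chis[i], sidechains[i] = saved_id, saved_chis, saved_sc
            trace.append(min(trace[-1], e_curr))

    identities, chis = list(best[1]), list(best[2])
    sidechains = {i: (dctx.sidechain_atoms(i, identities[i], chis[i])
                      if i != anchor and topo.get_topology(identities[i]).sidechain
                      else sidechains.get(i, {}))
                  for i in range(n)}
    if refine:
        identities, chis = _chi_refine(dctx, identities, chis, sidechains, anchor)

    # realize the final pose
    for i in range(n):
        if i == anchor:
            continue
        t = topo.get_topology(identities[i])
        r = pose.residues[i]
        keep = {k: r.atoms[k] for k in ("N", "CA", "C", "O", "H") if k in r.atoms}
        build_sidechain(keep, t, chis[i])
        pose.residues[i] = type(r)(t, keep)
    breakdown = score(pose, ctx, params, include_composition=True, bins=bins)
    report = interface_report(pose, ctx, params) if (compute_report and ctx) else None
    rec = DesignRecord(pose=pose, sequence=identities, chis=chis,
                       energy=breakdown, report=report, ring_size=n,
                       best_energy_trace=trace)
    log.info("designed %s  E=%.2f", rec.sequence_string(), breakdown.total)
    return rec


def _chi_refine(dctx, identities, chis, sidechains, anchor,
                span: float = 10.0, step: float = 2.5):
    """Local χ grid refinement (±span in step increments), one greedy pass."""
    for i in range(len(identities)):
        if i == anchor or not chis[i]:
            continue
        cur = list(chis[i])
        for k in range(len(cur)):
            best_val, best_e = cur[k], None
            for off in np.arange(-span, span + step / 2, step):
                cand = list(cur)
                cand[k] = cur[k] + off
                e = dctx.local_energy(i, identities[i], tuple(cand), sidechains)
                if best_e is None or e < best_e:
                    best_e, best_val = e, cand[k]
            cur[k] = best_val
        chis[i] = tuple(cur)
        sidechains[i] = dctx.sidechain_atoms(i, identities[i], chis[i])
    return identities, chis


def rank_designs(records: list[DesignRecord]) -> list[DesignRecord]:
    """Stable ordering: interaction energy, then buried SASA, shape
    complementarity and total H-bond count as tie-breakers."""
    for r in records:
        if r.report is None:
            raise RankingError("design record lacks interface metrics")
    return sorted(records, key=lambda r: (
        r.report.interaction_energy,
        -r.report.buried_sasa,
        -r.report.sc,
        -(r.report.inter_hbond_count + r.report.intra_hbond_count),
    ))
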