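"""Hotspot anchor residues: extraction from a bound partner, rotamer-scan
placement on a bare surface site, and poly-Gly arm extension.

The anchor is the one peptide residue whose coordinates stay fixed through
backbone sampling and sequence design; everything else is built around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import topology as topo
from .energy import DEFAULT_PARAMS, ScoreParams, as_context, has_clash, interaction_energy
from .exceptions import NoPlacementError, ParameterError, ResidueLookupError
from .geometry import PeptidePose, Residue, TorsionSet, build_chain, measure_dihedral
from .pdbio import TargetStructure
from .rotamers import scan_rotamer_set


@dataclass
class HotspotAnchor:
    """A fixed full-atom anchor residue."""

    identity: str
    chirality: str
    atoms: dict[str, np.ndarray]
    chis: tuple[float, ...]
    source: str  # "complex-extraction" | "rotamer-scan"

    def copy_atoms(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v, float).copy() for k, v in self.atoms.items()}


def _measure_chis(identity: str, atoms: dict[str, np.ndarray]) -> tuple[float, ...]:
    t = topo.get_topology(identity)
    chis = []
    for names in t.chi_atoms:
        if all(n in atoms for n in names):
            chis.append(measure_dihedral(*(atoms[n] for n in names)))
        else:
            break
    return tuple(chis)


def extract_hotspot(complex_structure: TargetStructure, partner_chain: str,
                    residue_number: int, icode: str = ""):
    """Copy one residue of the bound partner as the anchor; the remaining
    partner chain is discarded and the other chain(s) become the target.

    Returns ``(HotspotAnchor, TargetStructure)``.
    """
    idx = complex_structure.residue_indices(partner_chain, residue_number, icode)
    resname = str(complex_structure.resnames[idx[0]])
    atoms = {str(complex_structure.names[i]): complex_structure.coords[i].copy()
             for i in idx}
    for needed in ("N", "CA", "C"):
        if needed not in atoms:
            raise ResidueLookupError(
                f"hotspot residue {partner_chain}/{residue_number} lacks {needed}")
    t = topo.get_topology(resname)
    target = complex_structure.drop_chains(partner_chain)
    if target.n_atoms == 0:
        raise ResidueLookupError("no target chains remain after extraction")
    anchor = HotspotAnchor(
        identity=resname,
        chirality=t.chirality,
        atoms=atoms,
        chis=_measure_chis(resname, atoms),
        source="complex-extraction",
    )
    return anchor, target


def _build_placed_residue(identity: str, chis, site, normal, spin: float):
    """One residue with its Cα at ``site`` and side chain along −normal."""
    pose = build_chain([identity], [TorsionSet(-120.0, 120.0, 180.0, tuple(chis))])
    r = pose.residues[0]
    ca = r.atoms["CA"]
    if "CB" in r.atoms:
        axis_local = r.atoms["CB"] - ca
    else:
        axis_local = r.atoms["C"] - ca
    axis_local = axis_local / np.linalg.norm(axis_local)
    z = -np.asarray(normal, float)
    z = z / np.linalg.norm(z)
    # reference perpendicular, rotated by the user's spin angle
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(z)))] = 1.0
    x = np.cross(z, ref)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    sp = np.radians(spin)
    x_spin = np.cos(sp) * x + np.sin(sp) * y
    y_spin = np.cross(z, x_spin)
    # local frame: axis_local plus perpendicular from the N direction
    n_local = r.atoms["N"] - ca
    px = n_local - np.dot(n_local, axis_local) * axis_local
    px /= np.linalg.norm(px)
    py = np.cross(axis_local, px)
    B_local = np.column_stack([px, py, axis_local])
    B_world = np.column_stack([x_spin, y_spin, z])
    R = B_world @ B_local.T
    atoms = {k: np.asarray(site, float) + R @ (v - ca) for k, v in r.atoms.items()}
    return atoms


def rotamer_scan_place(target, identity: str, site, normal, spin: float = 0.0,
                       rotamer_set=None, params: ScoreParams = DEFAULT_PARAMS):
    """Place an anchor residue at a user-chosen surface site by scanning a
    rotamer set and keeping the lowest-energy clash-free rotamer.

    Ties break lexicographically on (χ1, χ2, ...).  Returns
    ``(HotspotAnchor, scan_report)`` where the report lists every scanned
    rotamer with its score and clash flag.
    """
    ctx = as_context(target)
    if rotamer_set is None:
        rotamer_set = scan_rotamer_set(identity)
    rotamer_set = list(rotamer_set)
    if not rotamer_set:
        raise NoPlacementError("empty rotamer set")
    report = []
    best = None
    for chis in rotamer_set:
        atoms = _build_placed_residue(identity, chis, site, normal, spin)
        heavy = [n for n in atoms if topo.element_of(n) != "H"]
        coords = np.array([atoms[n] for n in heavy])
        radii = np.array([topo.VDW_RADII[topo.element_of(n)] for n in heavy])
        clash = has_clash(coords, radii, ctx, frac=params.clash_frac)
        pose = PeptidePose([Residue(topo.get_topology(identity), atoms)])
        e = interaction_energy(pose, ctx, params)
        report.append({"chis": tuple(chis), "score": e, "clash": bool(clash)})
        if not clash:
            key = (e, tuple(chis))
            if best is None or key < best[0]:
                best = (key, chis, atoms)
    if best is None:
        raise NoPlacementError("every rotamer clashes with the target")
    _, chis, atoms = best
    t = topo.get_topology(identity)
    return HotspotAnchor(identity=identity, chirality=t.chirality, atoms=atoms,
                         chis=tuple(chis), source="rotamer-scan"), report


def extend_polygly(anchor: HotspotAnchor, n_nterm: int, n_cterm: int) -> PeptidePose:
    """Open chain: n_nterm Gly + anchor + n_cterm Gly, arms extended
    (φ = ψ = 180°), anchor atoms verbatim."""
    if not (3 <= n_nterm <= 6 and 3 <= n_cterm <= 6):
        raise ParameterError("poly-Gly arm lengths must be within [3, 6]")
    n = n_nterm + 1 + n_cterm
    topologies = ["GLY"] * n_nterm + [anchor.identity] + ["GLY"] * n_cterm
    torsions = [TorsionSet(180.0, 180.0, 180.0, ()) for _ in range(n)]
    torsions[n_nterm] = TorsionSet(180.0, 180.0, 180.0, ())
    return build_chain(topologies, torsions,
                       anchor={k: anchor.atoms[k] for k in ("N", "CA", "C")},
                       anchor_index=n_nterm, cyclic=False,
                       anchor_all_atoms=anchor.copy_atoms())
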