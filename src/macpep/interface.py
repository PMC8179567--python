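"""Protein–peptide interface metrics.

Solvent-accessible surface area by the Shrake–Rupley dot-sphere method,
buried interface area as SASA(a) + SASA(b) − SASA(a∪b), and the
Lawrence–Colman shape-complementarity statistic Sc computed on van der Waals
dot surfaces with nearest-dot pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from . import topology as topo
from .exceptions import ScoringError, UndefinedInterfaceError
from .geometry import PeptidePose
from .pdbio import TargetStructure, structure_from_pose

DEFAULT_PROBE = 1.4      # Å, water probe
DEFAULT_DOTS = 960       # dots per atom
SC_WEIGHT = 0.5          # Å⁻², Lawrence–Colman distance weight
SC_INTERFACE_CUTOFF = 1.5  # Å, band from the opposing surface


@dataclass
class InterfaceReport:
    """Ranking metrics of one peptide–target complex."""

    buried_sasa: float
    sc: float
    inter_hbond_count: int
    intra_hbond_count: int
    interaction_energy: float

    def as_dict(self) -> dict:
        return {
            "buried_sasa": self.buried_sasa,
            "sc": self.sc,
            "inter_hbond_count": self.inter_hbond_count,
            "intra_hbond_count": self.intra_hbond_count,
            "interaction_energy": self.interaction_energy,
        }


@lru_cache(maxsize=16)
def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _coords_radii(obj):
    """Accept a TargetStructure, PeptidePose or (coords, radii) pair."""
    if isinstance(obj, TargetStructure):
        heavy = np.array([e != "H" for e in obj.elements])
        return obj.coords[heavy], obj.radii[heavy]
    if isinstance(obj, PeptidePose):
        s = structure_from_pose(obj)
        return _coords_radii(s)
    coords, radii = obj
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if len(coords) != len(radii):
        raise ScoringError("coords and radii length mismatch")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ScoringError("every atom needs a positive radius")
    return coords, radii


def sasa(obj, probe_radius: float = DEFAULT_PROBE, dot_density: int = DEFAULT_DOTS):
    """Per-atom and total solvent-accessible surface area (Å²).

    Returns ``(per_atom, total)``.
    """
    coords, radii = _coords_radii(obj)
    if probe_radius <= 0:
        raise ScoringError("probe radius must be positive")
    n = len(coords)
    if n == 0:
        raise ScoringError("empty atom selection")
    dots = _fibonacci_sphere(int(dot_density))
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    per_atom = np.zeros(n)
    rmax = expanded.max()
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * dots
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        exposed = np.ones(len(dots), bool)
        for j in nbrs:
            rj = expanded[j]
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > rj * rj
            if not exposed.any():
                break
        per_atom[i] = 4.0 * np.pi * ri * ri * exposed.sum() / len(dots)
    return per_atom, float(per_atom.sum())


def buried_interface_area(a, b, probe_radius: float = DEFAULT_PROBE,
                          dot_density: int = DEFAULT_DOTS) -> float:
    """Two-sided buried area: SASA(a) + SASA(b) − SASA(a∪b) (Å²)."""
    ca, ra = _coords_radii(a)
    cb, rb = _coords_radii(b)
    _, sa = sasa((ca, ra), probe_radius, dot_density)
    _, sb = sasa((cb, rb), probe_radius, dot_density)
    _, sab = sasa((np.vstack([ca, cb]), np.concatenate([ra, rb])),
                  probe_radius, dot_density)
    return float(sa + sb - sab)


def _vdw_dot_surface(coords, radii, dot_density):
    """Exposed van der Waals surface dots of one body with outward normals."""
    dots = _fibonacci_sphere(int(dot_density))
    tree = cKDTree(coords)
    rmax = radii.max()
    points, normals, weights = [], [], []
    for i in range(len(coords)):
        ri = radii[i]
        pts = coords[i] + ri * dots
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        exposed = np.ones(len(dots), bool)
        for j in nbrs:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] * radii[j]
            if not exposed.any():
                break
        if exposed.any():
            points.append(pts[exposed])
            normals.append(dots[exposed])
            weights.append(np.full(exposed.sum(), ri * ri))
    if not points:
        raise UndefinedInterfaceError("no exposed surface dots")
    return np.vstack(points), np.vstack(normals), np.concatenate(weights)


def shape_complementarity(a, b, interface_cutoff: float = SC_INTERFACE_CUTOFF,
                          weight: float = SC_WEIGHT,
                          dot_density: int = DEFAULT_DOTS) -> float:
    """Lawrence–Colman shape complementarity Sc ∈ [−1, 1].

    For every interface dot x on surface A with nearest opposing dot x′:
    S(x) = (n̂(x) · −n̂(x′)) · exp(−w·|x−x′|²); Sc is the mean of the two
    per-surface medians.  Raises :class:`UndefinedInterfaceError` when the
    bodies share no interface dots within the cutoff band.
    """
    ca, ra = _coords_radii(a)
    cb, rb = _coords_radii(b)
    pa, na, _ = _vdw_dot_surface(ca, ra, dot_density)
    pb, nb, _ = _vdw_dot_surface(cb, rb, dot_density)
    tree_a = cKDTree(pa)
    tree_b = cKDTree(pb)

    def side(points, normals, other_tree, other_normals):
        d, idx = other_tree.query(points, k=1)
        mask = d <= interface_cutoff
        if not mask.any():
            return None
        dot = -np.einsum("ij,ij->i", normals[mask], other_normals[idx[mask]])
        return dot * np.exp(-weight * d[mask] ** 2)

    s_ab = side(pa, na, tree_b, nb)
    s_ba = side(pb, nb, tree_a, na)
    if s_ab is None or s_ba is None:
        raise UndefinedInterfaceError("bodies are not in contact")
    return float((np.median(s_ab) + np.median(s_ba)) / 2.0)


def interface_report(pose: PeptidePose, target, params=None) -> InterfaceReport:
    """All ranking metrics for a designed pose against its target."""
    from .energy import DEFAULT_PARAMS, as_context, detect_hbonds, interaction_energy

    params = params or DEFAULT_PARAMS
    ctx = as_context(target)
    records = detect_hbonds(pose, ctx, params)
    inter = sum(1 for r in records if r.class_ == "intermolecular")
    intra = sum(1 for r in records if r.class_.startswith("intramolecular"))
    buried = buried_interface_area(pose, ctx.structure)
    try:
        sc = shape_complementarity(pose, ctx.structure)
    except UndefinedInterfaceError:
        sc = 0.0
    return InterfaceReport(
        buried_sasa=buried,
        sc=sc,
        inter_hbond_count=inter,
        intra_hbond_count=intra,
        interaction_energy=interaction_energy(pose, ctx, params),
    )
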