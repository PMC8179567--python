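"""Internal-coordinate peptide geometry.

Chains are constructed by sequential internal-to-Cartesian placement
(NeRF-style three-atom frame extension) from ideal bond lengths and angles;
all torsions follow the IUPAC sign convention (eclipsed = 0°, angles in
degrees, values wrapped to (−180°, 180°]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import topology as topo
from .exceptions import (
    AtomMappingError,
    GeometryError,
    InsufficientPointsError,
    InvalidTorsionError,
)

_COLLINEAR_TOL = 1e-10


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees to (−180, 180]."""
    w = (a + 180.0) % 360.0 - 180.0
    if w <= -180.0:
        w += 360.0
    return w


def measure_angle(p1, p2, p3) -> float:
    """Bond angle at p2 in degrees."""
    u = np.asarray(p1, float) - p2
    v = np.asarray(p3, float) - p2
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, IUPAC convention.

    Raises :class:`GeometryError` when three consecutive points are
    (numerically) collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1)
    norm2 = np.linalg.norm(n2)
    scale1 = np.linalg.norm(b1) * np.linalg.norm(b2)
    scale2 = np.linalg.norm(b2) * np.linalg.norm(b3)
    if scale1 == 0 or scale2 == 0 or norm1 < _COLLINEAR_TOL * scale1 \
            or norm2 < _COLLINEAR_TOL * scale2:
        raise GeometryError("collinear or coincident points in dihedral")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D bonded to ``c`` given internal coordinates.

    ``angle`` is the bond angle b-c-D, ``dihedral`` the torsion a-b-c-D
    (degrees).  Consistent with :func:`measure_dihedral` so that build and
    measure round-trip exactly.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle)
    chi = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise GeometryError("collinear frame atoms in placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi),
         bond * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Atom / residue / pose containers
# ---------------------------------------------------------------------------


@dataclass
class AtomRecord:
    """A single atom: PDB name, element, coordinates (Å)."""

    name: str
    element: str
    coords: np.ndarray
    residue_index: int
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError(f"non-finite coordinates for atom {self.name}")


class Residue:
    """One residue: topology reference plus a name → coordinate map."""

    __slots__ = ("topology", "atoms")

    def __init__(self, topology: topo.ResidueTopology, atoms: dict[str, np.ndarray]):
        self.topology = topology
        self.atoms = {k: np.asarray(v, float) for k, v in atoms.items()}

    @property
    def identity(self) -> str:
        return self.topology.name3

    @property
    def chirality(self) -> str:
        return self.topology.chirality

    def heavy_atom_names(self) -> list[str]:
        names = [n for n in topo.BACKBONE_HEAVY if n in self.atoms]
        names += [a.name for a in self.topology.sidechain if a.name in self.atoms]
        return names

    def copy(self) -> "Residue":
        return Residue(self.topology, {k: v.copy() for k, v in self.atoms.items()})


class PeptidePose:
    """Ordered residues of a (possibly cyclic) peptide.

    ``anchor_mask[i]`` marks residues whose coordinates are immutable under
    every pose-producing operation (the design hotspot).
    """

    def __init__(self, residues: Sequence[Residue], cyclic: bool = False,
                 anchor_mask: Sequence[bool] | None = None):
        self.residues = list(residues)
        self.cyclic = bool(cyclic)
        if anchor_mask is None:
            anchor_mask = [False] * len(self.residues)
        if len(anchor_mask) != len(self.residues):
            raise ValueError("anchor_mask length mismatch")
        self.anchor_mask = list(anchor_mask)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def anchor_index(self) -> int | None:
        for i, flag in enumerate(self.anchor_mask):
            if flag:
                return i
        return None

    # -- torsions ----------------------------------------------------------

    def _res(self, i: int) -> Residue:
        return self.residues[i % len(self.residues)]

    def _neighbor(self, i: int, step: int) -> Residue | None:
        j = i + step
        if self.cyclic:
            return self._res(j)
        if 0 <= j < len(self.residues):
            return self.residues[j]
        return None

    def phi(self, i: int) -> float | None:
        prev = self._neighbor(i, -1)
        if prev is None:
            return None
        r = self.residues[i]
        return measure_dihedral(prev.atoms["C"], r.atoms["N"], r.atoms["CA"], r.atoms["C"])

    def psi(self, i: int) -> float | None:
        nxt = self._neighbor(i, +1)
        if nxt is None:
            return None
        r = self.residues[i]
        return measure_dihedral(r.atoms["N"], r.atoms["CA"], r.atoms["C"], nxt.atoms["N"])

    def omega(self, i: int) -> float | None:
        prev = self._neighbor(i, -1)
        if prev is None:
            return None
        r = self.residues[i]
        return measure_dihedral(prev.atoms["CA"], prev.atoms["C"], r.atoms["N"], r.atoms["CA"])

    def chi(self, i: int, k: int) -> float:
        r = self.residues[i]
        if k < 1 or k > r.topology.n_chi:
            raise InvalidTorsionError(f"{r.identity} has no chi{k}")
        names = r.topology.chi_atoms[k - 1]
        return measure_dihedral(*(r.atoms[n] for n in names))

    def chis(self, i: int) -> tuple[float, ...]:
        return tuple(self.chi(i, k) for k in range(1, self.residues[i].topology.n_chi + 1))

    # -- atoms -------------------------------------------------------------

    def atom_entries(self, selection: str = "all-heavy") -> list[tuple[int, str]]:
        """Deterministic (residue_index, atom_name) list under a selection."""
        out: list[tuple[int, str]] = []
        for i, r in enumerate(self.residues):
            if selection == "backbone-heavy":
                names: Iterable[str] = [n for n in topo.BACKBONE_HEAVY if n in r.atoms]
            elif selection == "all-heavy":
                names = r.heavy_atom_names()
            elif selection == "all":
                names = [n for n in topo.BACKBONE_HEAVY if n in r.atoms]
                if "H" in r.atoms:
                    names.append("H")
                names += [a.name for a in r.topology.sidechain if a.name in r.atoms]
            else:
                raise ValueError(f"unknown selection {selection!r}")
            out.extend((i, n) for n in names)
        return out

    def coords_array(self, selection: str = "all-heavy") -> np.ndarray:
        entries = self.atom_entries(selection)
        return np.array([self.residues[i].atoms[n] for i, n in entries])

    def sequence3(self) -> list[str]:
        return [r.identity for r in self.residues]

    def sequence_string(self) -> str:
        """One-letter sequence; D residues lowercase, Gly 'G'."""
        out = []
        for r in self.residues:
            letter = r.topology.one_letter
            out.append(letter)
        return "".join(out)

    def copy(self) -> "PeptidePose":
        return PeptidePose([r.copy() for r in self.residues], self.cyclic,
                           list(self.anchor_mask))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PeptidePose":
        """Rigid motion of the whole pose (anchor moves with it)."""
        p = self.copy()
        for r in p.residues:
            for k in r.atoms:
                r.atoms[k] = rotation @ r.atoms[k] + translation
        return p

    def mirrored(self) -> "PeptidePose":
        """Exact mirror image: z-negated coordinates, mirrored identities."""
        residues = []
        for r in self.residues:
            t = topo.get_topology(topo.mirror_identity(r.identity))
            residues.append(Residue(t, {k: v * np.array([1.0, 1.0, -1.0])
                                        for k, v in r.atoms.items()}))
        return PeptidePose(residues, self.cyclic, list(self.anchor_mask))

    def closure_residual(self) -> dict[str, float]:
        """Geometry error of the ring-closing C(n-1)→N(0) bond."""
        if not self.cyclic:
            raise GeometryError("closure residual undefined for open chains")
        last = self.residues[-1]
        first = self.residues[0]
        bond = float(np.linalg.norm(last.atoms["C"] - first.atoms["N"]))
        ang1 = measure_angle(last.atoms["CA"], last.atoms["C"], first.atoms["N"])
        ang2 = measure_angle(last.atoms["C"], first.atoms["N"], first.atoms["CA"])
        om = measure_dihedral(last.atoms["CA"], last.atoms["C"],
                              first.atoms["N"], first.atoms["CA"])
        return {
            "bond_error": abs(bond - topo.BOND_C_N),
            "angle_error": max(abs(ang1 - topo.ANGLE_CA_C_N), abs(ang2 - topo.ANGLE_C_N_CA)),
            "omega_error": abs(wrap_angle(om - 180.0)),
            "bond_length": bond,
        }


# ---------------------------------------------------------------------------
# Chain building
# ---------------------------------------------------------------------------


@dataclass
class TorsionSet:
    """Backbone + side-chain torsions of one residue (degrees)."""

    phi: float = 180.0
    psi: float = 180.0
    omega: float = 180.0
    chis: tuple[float, ...] = ()


def _build_backbones(topologies, torsions, anchor_atoms, anchor_index):
    n = len(topologies)
    bb: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]
    if anchor_atoms is None:
        theta = np.radians(topo.ANGLE_N_CA_C)
        bb[anchor_index] = {
            "N": np.zeros(3),
            "CA": np.array([topo.BOND_N_CA, 0.0, 0.0]),
            "CA_C_dir": None,
        }
        bb[anchor_index]["C"] = bb[anchor_index]["CA"] + topo.BOND_CA_C * np.array(
            [-np.cos(theta), np.sin(theta), 0.0])
        del bb[anchor_index]["CA_C_dir"]
    else:
        bb[anchor_index] = {k: np.asarray(v, float) for k, v in anchor_atoms.items()
                            if k in ("N", "CA", "C")}
    # forward: anchor+1 .. n-1
    for i in range(anchor_index + 1, n):
        p = bb[i - 1]
        t_prev = torsions[i - 1]
        t = torsions[i]
        N = place_atom(p["N"], p["CA"], p["C"], topo.BOND_C_N, topo.ANGLE_CA_C_N, t_prev.psi)
        CA = place_atom(p["CA"], p["C"], N, topo.BOND_N_CA, topo.ANGLE_C_N_CA, t.omega)
        C = place_atom(p["C"], N, CA, topo.BOND_CA_C, topo.ANGLE_N_CA_C, t.phi)
        bb[i] = {"N": N, "CA": CA, "C": C}
    # backward: anchor-1 .. 0
    for i in range(anchor_index - 1, -1, -1):
        nx = bb[i + 1]
        t_next = torsions[i + 1]
        t = torsions[i]
        C = place_atom(nx["C"], nx["CA"], nx["N"], topo.BOND_C_N, topo.ANGLE_C_N_CA, t_next.phi)
        CA = place_atom(nx["CA"], nx["N"], C, topo.BOND_CA_C, topo.ANGLE_CA_C_N, t_next.omega)
        N = place_atom(nx["N"], C, CA, topo.BOND_N_CA, topo.ANGLE_N_CA_C, t.psi)
        bb[i] = {"N": N, "CA": CA, "C": C}
    return bb


def build_sidechain(atoms: dict[str, np.ndarray], topology: topo.ResidueTopology,
                    chis: Sequence[float]) -> None:
    """Append side-chain heavy atoms to ``atoms`` in place."""
    if chis and topology.n_chi == 0 and topology.name3 not in ("PRO", "DPR"):
        if topology.name3 == "GLY":
            raise InvalidTorsionError("chi torsions requested for Gly")
    if len(chis) > topology.n_chi:
        raise InvalidTorsionError(
            f"{topology.name3} defines {topology.n_chi} chi angles, got {len(chis)}")
    full_chis = list(chis) + [180.0] * (topology.n_chi - len(chis))
    for entry in topology.sidechain:
        kind = entry.dihedral[0]
        if kind == "fixed":
            dih = entry.dihedral[1]
        else:
            _, k, offset = entry.dihedral
            dih = full_chis[k - 1] + offset
        a, b, c = (atoms[p] for p in entry.parents)
        atoms[entry.name] = place_atom(a, b, c, entry.bond, entry.angle, dih)


def build_chain(topologies: Sequence[topo.ResidueTopology | str],
                torsions: Sequence[TorsionSet],
                anchor: dict[str, np.ndarray] | None = None,
                anchor_index: int = 0,
                cyclic: bool = False,
                anchor_all_atoms: dict[str, np.ndarray] | None = None) -> PeptidePose:
    """Build a peptide pose from per-residue torsions and ideal geometry.

    If ``anchor`` (a name → coordinate map containing at least N, CA, C) is
    given, the chain grows bidirectionally from residue ``anchor_index``
    whose coordinates are taken verbatim; ``anchor_all_atoms`` may carry the
    anchor's full atom set (side chain included) for pass-through.
    """
    topologies = [topo.get_topology(t) if isinstance(t, str) else t for t in topologies]
    if len(topologies) != len(torsions):
        raise ValueError("torsion list length must match topology list")
    n = len(topologies)
    bb = _build_backbones(topologies, torsions, anchor, anchor_index)

    residues: list[Residue] = []
    for i, t in enumerate(topologies):
        atoms = dict(bb[i])
        is_anchor = anchor is not None and i == anchor_index
        # carbonyl O
        nxt = bb[(i + 1) % n] if (cyclic or i + 1 < n) else None
        if is_anchor and anchor_all_atoms and "O" in anchor_all_atoms:
            atoms["O"] = np.asarray(anchor_all_atoms["O"], float)
        elif nxt is not None:
            atoms["O"] = place_atom(nxt["N"], atoms["CA"], atoms["C"],
                                    topo.BOND_C_O, topo.ANGLE_CA_C_O, 180.0)
        else:
            atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                    topo.BOND_C_O, topo.ANGLE_CA_C_O,
                                    torsions[i].psi + 180.0)
        # amide H
        if t.has_amide_h:
            prev = bb[(i - 1) % n] if (cyclic or i > 0) else None
            ref = prev["C"] if prev is not None else atoms["C"]
            atoms["H"] = place_atom(ref, atoms["CA"], atoms["N"],
                                    topo.BOND_N_H, topo.ANGLE_CA_N_H, 180.0)
        # side chain
        if is_anchor and anchor_all_atoms:
            for k, v in anchor_all_atoms.items():
                if k not in ("N", "CA", "C", "O"):
                    atoms[k] = np.asarray(v, float)
        else:
            build_sidechain(atoms, t, torsions[i].chis)
        residues.append(Residue(t, atoms))

    mask = [False] * n
    if anchor is not None:
        mask[anchor_index] = True
    return PeptidePose(residues, cyclic=cyclic, anchor_mask=mask)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (proper rotation only).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise AtomMappingError("point sets must share shape (n, 3)")
    if len(mobile) < 3:
        raise InsufficientPointsError("need at least 3 points for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    diff = (mobile - mc) @ R.T - (reference - rc)
    rmsd = float(np.sqrt((diff ** 2).sum() / len(mobile)))
    return R, t, rmsd


def pose_rmsd(a: PeptidePose, b: PeptidePose,
              atom_selection: str = "backbone-heavy") -> float:
    """Superposition-minimized RMSD over a named atom selection."""
    ea = a.atom_entries(atom_selection)
    eb = b.atom_entries(atom_selection)
    if ea != eb:
        raise AtomMappingError("atom selections of the two poses do not match")
    xa = np.array([a.residues[i].atoms[n] for i, n in ea])
    xb = np.array([b.residues[i].atoms[n] for i, n in eb])
    return superpose_kabsch(xa, xb)[2]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
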