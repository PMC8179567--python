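"""Residue topologies: ideal backbone geometry, side-chain z-matrices, chirality.

All internal coordinates are Engh–Huber-style ideal values (lengths in Å,
angles in degrees).  A D-amino-acid topology is the exact mirror image of its
L partner: every dihedral offset in the side-chain z-matrix (including the
Cβ-placement improper) changes sign, so that building a D residue with
sign-negated (φ, ψ, χ) torsions yields the mirror image of the L residue
built with the originals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# Ideal backbone geometry (lengths Å, angles deg)
# ---------------------------------------------------------------------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_CA_N_H = 118.2

# Cβ placement improper: dihedral N-C-CA-CB, positive for L residues.
CB_IMPROPER = 122.6
BOND_CA_CB = 1.530
ANGLE_C_CA_CB = 110.1

BACKBONE_HEAVY = ("N", "CA", "C", "O")

#: all-trans Cα(i)–Cα(i+1) distance is ~3.80 Å with these values


@dataclass(frozen=True)
class SidechainAtom:
    """One z-matrix entry.  ``dihedral`` is either ``("chi", k, offset)`` —
    the torsion equals χ_k plus a fixed offset — or ``("fixed", value)``.
    Offsets and fixed values are stored for the L topology and are negated
    for the D mirror."""

    name: str
    parents: tuple[str, str, str]  # (A, B, C); the new atom bonds to C
    bond: float
    angle: float
    dihedral: tuple


def _sc(name, parents, bond, angle, dihedral):
    return SidechainAtom(name, tuple(parents), bond, angle, tuple(dihedral))


@dataclass(frozen=True)
class ResidueTopology:
    """Identity + chirality + side-chain construction recipe."""

    name3: str
    one_letter: str
    chirality: str  # "L" | "D" | "achiral"
    sidechain: tuple[SidechainAtom, ...] = ()
    chi_atoms: tuple[tuple[str, str, str, str], ...] = ()
    extra_bonds: tuple[tuple[str, str], ...] = ()  # ring-closing bonds
    has_amide_h: bool = True
    phi_range: tuple[float, float] | None = None  # Pro constraint

    @property
    def n_chi(self) -> int:
        return len(self.chi_atoms)

    @property
    def has_cb(self) -> bool:
        return any(a.name == "CB" for a in self.sidechain)

    def heavy_sidechain_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.sidechain)


def element_of(atom_name: str) -> str:
    """Element from a PDB atom name (single-letter elements only)."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


# ---------------------------------------------------------------------------
# L side-chain z-matrices
# ---------------------------------------------------------------------------

_CB = _sc("CB", ("N", "C", "CA"), BOND_CA_CB, ANGLE_C_CA_CB, ("fixed", CB_IMPROPER))

_SIDECHAINS: dict[str, tuple[list, list, list]] = {
    # name: (z-matrix after CB, chi definitions, extra ring bonds)
    "GLY": ([], [], []),
    "ALA": ([], [], []),
    "SER": (
        [_sc("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
        [("N", "CA", "CB", "OG")],
        [],
    ),
    "CYS": (
        [_sc("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
        [("N", "CA", "CB", "SG")],
        [],
    ),
    "THR": (
        [
            _sc("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1, 0.0)),
            _sc("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0)),
        ],
        [("N", "CA", "CB", "OG1")],
        [],
    ),
    "VAL": (
        [
            _sc("CG1", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, 0.0)),
            _sc("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, 122.0)),
        ],
        [("N", "CA", "CB", "CG1")],
        [],
    ),
    "LEU": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
            _sc("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
            _sc("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 122.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
        [],
    ),
    "ILE": (
        [
            _sc("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
            _sc("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
            _sc("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0)),
        ],
        [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
        [],
    ),
    "PHE": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
            _sc("CD1", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
            _sc("CD2", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
            _sc("CE1", ("CB", "CG", "CD1"), 1.382, 121.1, ("fixed", 180.0)),
            _sc("CE2", ("CB", "CG", "CD2"), 1.382, 121.1, ("fixed", 180.0)),
            _sc("CZ", ("CG", "CD1", "CE1"), 1.382, 119.9, ("fixed", 0.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
        [("CZ", "CE2")],
    ),
    "TYR": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.512, 113.9, ("chi", 1, 0.0)),
            _sc("CD1", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 2, 0.0)),
            _sc("CD2", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 2, 180.0)),
            _sc("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, ("fixed", 180.0)),
            _sc("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, ("fixed", 180.0)),
            _sc("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, ("fixed", 0.0)),
            _sc("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("fixed", 180.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
        [("CZ", "CE2")],
    ),
    "TRP": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1, 0.0)),
            _sc("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
            _sc("CD2", ("CA", "CB", "CG"), 1.433, 126.7, ("chi", 2, 180.0)),
            _sc("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, ("fixed", 180.0)),
            _sc("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, ("fixed", 180.0)),
            _sc("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, ("fixed", 0.0)),
            _sc("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, ("fixed", 180.0)),
            _sc("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.7, ("fixed", 180.0)),
            _sc("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, ("fixed", 0.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
        [("NE1", "CE2"), ("CZ3", "CH2")],
    ),
    "HIS": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1, 0.0)),
            _sc("ND1", ("CA", "CB", "CG"), 1.371, 122.7, ("chi", 2, 0.0)),
            _sc("CD2", ("CA", "CB", "CG"), 1.356, 131.1, ("chi", 2, 180.0)),
            _sc("CE1", ("CB", "CG", "ND1"), 1.319, 109.0, ("fixed", 180.0)),
            _sc("NE2", ("CB", "CG", "CD2"), 1.374, 107.1, ("fixed", 180.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
        [("CE1", "NE2")],
    ),
    "ASP": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.516, 113.0, ("chi", 1, 0.0)),
            _sc("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
            _sc("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
        [],
    ),
    "ASN": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.516, 112.7, ("chi", 1, 0.0)),
            _sc("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
            _sc("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
        [],
    ),
    "GLU": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            _sc("CD", ("CA", "CB", "CG"), 1.516, 113.0, ("chi", 2, 0.0)),
            _sc("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
            _sc("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
        [],
    ),
    "GLN": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            _sc("CD", ("CA", "CB", "CG"), 1.516, 112.7, ("chi", 2, 0.0)),
            _sc("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
            _sc("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
        [],
    ),
    "LYS": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            _sc("CD", ("CA", "CB", "CG"), 1.530, 111.3, ("chi", 2, 0.0)),
            _sc("CE", ("CB", "CG", "CD"), 1.530, 111.3, ("chi", 3, 0.0)),
            _sc("NZ", ("CG", "CD", "CE"), 1.489, 112.0, ("chi", 4, 0.0)),
        ],
        [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"),
            ("CG", "CD", "CE", "NZ"),
        ],
        [],
    ),
    "ARG": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            _sc("CD", ("CA", "CB", "CG"), 1.530, 111.3, ("chi", 2, 0.0)),
            _sc("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
            _sc("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4, 0.0)),
            _sc("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 0.0)),
            _sc("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 180.0)),
        ],
        [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"),
            ("CG", "CD", "NE", "CZ"),
        ],
        [],
    ),
    "MET": (
        [
            _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            _sc("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
            _sc("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3, 0.0)),
        ],
        [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
        [],
    ),
    "PRO": (
        # Rigid, puckered pyrrolidine ring; no rotamers.
        [
            _sc("CG", ("N", "CA", "CB"), 1.492, 104.5, ("fixed", 28.5)),
            _sc("CD", ("CA", "CB", "CG"), 1.503, 106.1, ("fixed", -39.0)),
        ],
        [],
        [("CD", "N")],
    ),
}

# D residue CCD codes <-> parent L identities
D_CODES = {
    "DAL": "ALA",
    "DPR": "PRO",
    "DPN": "PHE",
    "DTR": "TRP",
    "DTY": "TYR",
    "DSN": "SER",
    "DTH": "THR",
    "DVA": "VAL",
    "DLE": "LEU",
    "DIL": "ILE",
    "DAS": "ASP",
    "DGL": "GLU",
    "DSG": "ASN",
    "DGN": "GLN",
    "DLY": "LYS",
    "DAR": "ARG",
    "DHI": "HIS",
    "DCY": "CYS",
    "MED": "MET",
}
L_TO_D_CODE = {v: k for k, v in D_CODES.items()}

ONE_LETTER = {
    "GLY": "G", "ALA": "A", "SER": "S", "CYS": "C", "THR": "T", "VAL": "V",
    "LEU": "L", "ILE": "I", "PHE": "F", "TYR": "Y", "TRP": "W", "HIS": "H",
    "ASP": "D", "ASN": "N", "GLU": "E", "GLN": "Q", "LYS": "K", "ARG": "R",
    "MET": "M", "PRO": "P",
}


def _mirror_sidechain(entries: tuple[SidechainAtom, ...]) -> tuple[SidechainAtom, ...]:
    out = []
    for a in entries:
        if a.dihedral[0] == "chi":
            dih = ("chi", a.dihedral[1], -a.dihedral[2])
        else:
            dih = ("fixed", -a.dihedral[1])
        out.append(SidechainAtom(a.name, a.parents, a.bond, a.angle, dih))
    return tuple(out)


def _build_registry() -> dict[str, ResidueTopology]:
    reg: dict[str, ResidueTopology] = {}
    for name, (tail, chis, rings) in _SIDECHAINS.items():
        if name == "GLY":
            reg[name] = ResidueTopology(name, "G", "achiral")
            continue
        sidechain = (_CB, *tail)
        topo = ResidueTopology(
            name3=name,
            one_letter=ONE_LETTER[name],
            chirality="L",
            sidechain=sidechain,
            chi_atoms=tuple(tuple(c) for c in chis),
            extra_bonds=tuple(tuple(b) for b in rings),
            has_amide_h=(name != "PRO"),
            phi_range=(-75.0, -55.0) if name == "PRO" else None,
        )
        reg[name] = topo
        dcode = L_TO_D_CODE.get(name)
        if dcode:
            reg[dcode] = ResidueTopology(
                name3=dcode,
                one_letter=ONE_LETTER[name].lower(),
                chirality="D",
                sidechain=_mirror_sidechain(sidechain),
                chi_atoms=topo.chi_atoms,
                extra_bonds=topo.extra_bonds,
                has_amide_h=topo.has_amide_h,
                phi_range=(55.0, 75.0) if name == "PRO" else None,
            )
    return reg


TOPOLOGIES: dict[str, ResidueTopology] = _build_registry()

#: canonical L identities (3-letter) that have a D mirror
L_IDENTITIES = tuple(sorted(L_TO_D_CODE))


def get_topology(name3: str) -> ResidueTopology:
    try:
        return TOPOLOGIES[name3.upper()]
    except KeyError:
        raise UnknownResidue(name3) from None


class UnknownResidue(KeyError):
    pass


def mirror_identity(name3: str) -> str:
    """The opposite-chirality 3-letter code (GLY maps to itself)."""
    name3 = name3.upper()
    if name3 == "GLY":
        return "GLY"
    if name3 in D_CODES:
        return D_CODES[name3]
    return L_TO_D_CODE[name3]


# Bondi-style van der Waals radii (Å)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
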