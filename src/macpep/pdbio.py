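"""PDB input/output for targets, peptides and complexes.

Reading goes through gemmi (PDB v3.3 fixed columns, .pdb/.pdb.gz/.cif);
writing is done in-package so the ATOM/TER/LINK column layout, D-amino-acid
residue codes and the head-to-tail LINK record are bit-exact.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import topology as topo
from .exceptions import PDBParseError, ResidueLookupError, UnknownResidueError
from .geometry import PeptidePose, Residue

log = logging.getLogger(__name__)

#: residue names accepted on input: the 20 L amino acids + D counterparts
KNOWN_RESIDUES = frozenset(topo.ONE_LETTER) | frozenset(topo.D_CODES)

_SUPPORTED_ELEMENTS = frozenset(topo.VDW_RADII)


@dataclass(frozen=True)
class TargetStructure:
    """Immutable protein coordinates with per-atom vdW radii.

    Atoms are stored as parallel arrays ordered as read (chain, residue,
    atom).  Waters and non-amino-acid heteroatoms are excluded on load.
    """

    coords: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resseqs: np.ndarray
    icodes: np.ndarray
    chain_ids: np.ndarray
    occupancies: np.ndarray
    b_factors: np.ndarray
    radii: np.ndarray
    source: str = ""

    def __post_init__(self):
        for arr in (self.coords, self.radii, self.resseqs, self.occupancies,
                    self.b_factors):
            arr.setflags(write=False)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def select_chains(self, chains) -> "TargetStructure":
        if isinstance(chains, str):
            chains = [chains]
        mask = np.isin(self.chain_ids, list(chains))
        return self._subset(mask)

    def drop_chains(self, chains) -> "TargetStructure":
        if isinstance(chains, str):
            chains = [chains]
        mask = ~np.isin(self.chain_ids, list(chains))
        return self._subset(mask)

    def _subset(self, mask) -> "TargetStructure":
        return TargetStructure(
            coords=self.coords[mask].copy(),
            names=self.names[mask].copy(),
            elements=self.elements[mask].copy(),
            resnames=self.resnames[mask].copy(),
            resseqs=self.resseqs[mask].copy(),
            icodes=self.icodes[mask].copy(),
            chain_ids=self.chain_ids[mask].copy(),
            occupancies=self.occupancies[mask].copy(),
            b_factors=self.b_factors[mask].copy(),
            radii=self.radii[mask].copy(),
            source=self.source,
        )

    def residue_indices(self, chain: str, resseq: int, icode: str = "") -> np.ndarray:
        mask = ((self.chain_ids == chain) & (self.resseqs == resseq)
                & (self.icodes == icode))
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise ResidueLookupError(f"residue {chain}/{resseq}{icode} not found")
        return idx

    def iter_residues(self):
        """Yield (chain, resseq, icode, resname, atom index array)."""
        if self.n_atoms == 0:
            return
        start = 0
        for i in range(1, self.n_atoms + 1):
            if i == self.n_atoms or (
                self.chain_ids[i] != self.chain_ids[start]
                or self.resseqs[i] != self.resseqs[start]
                or self.icodes[i] != self.icodes[start]
            ):
                yield (str(self.chain_ids[start]), int(self.resseqs[start]),
                       str(self.icodes[start]), str(self.resnames[start]),
                       np.arange(start, i))
                start = i


def structure_from_atoms(atoms, source: str = "") -> TargetStructure:
    """Build a TargetStructure from an iterable of
    (chain, resseq, icode, resname, atom_name, element, xyz, occ, bfac)."""
    atoms = list(atoms)
    if not atoms:
        raise PDBParseError("no atoms given")
    return TargetStructure(
        coords=np.array([a[6] for a in atoms], float),
        names=np.array([a[4] for a in atoms], object),
        elements=np.array([a[5] for a in atoms], object),
        resnames=np.array([a[3] for a in atoms], object),
        resseqs=np.array([a[1] for a in atoms], int),
        icodes=np.array([a[2] for a in atoms], object),
        chain_ids=np.array([a[0] for a in atoms], object),
        occupancies=np.array([a[7] for a in atoms], float),
        b_factors=np.array([a[8] for a in atoms], float),
        radii=np.array([topo.VDW_RADII[a[5]] for a in atoms], float),
        source=source,
    )


def structure_from_pose(pose: PeptidePose, chain_id: str = "P",
                        start_resseq: int = 1) -> TargetStructure:
    """View a peptide pose as a TargetStructure (e.g. for interface metrics)."""
    rows = []
    for i, r in enumerate(pose.residues):
        for name in _pose_atom_order(r):
            el = topo.element_of(name)
            rows.append((chain_id, start_resseq + i, "", r.identity, name, el,
                         r.atoms[name], 1.0, 0.0))
    return structure_from_atoms(rows, source=f"pose:{pose.sequence_string()}")


def _pose_atom_order(residue: Residue) -> list[str]:
    names = [n for n in ("N", "CA", "C", "O") if n in residue.atoms]
    names += [a.name for a in residue.topology.sidechain if a.name in residue.atoms]
    if "H" in residue.atoms:
        names.append("H")
    return names


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_pdb(path, chain_filter=None, strict_unknown: bool = False) -> TargetStructure:
    """Read a PDB (or mmCIF) file into a TargetStructure.

    Only amino-acid residues from the supported set (20 L + D counterparts)
    are retained; waters and other heteroatoms are dropped.  Alternate
    locations resolve to the highest occupancy (ties → altloc 'A'); only the
    first model of multi-model entries is used.
    """
    import gemmi

    if not os.path.exists(str(path)):
        raise PDBParseError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"no models in {path}")
    model = st[0]

    if isinstance(chain_filter, str):
        chain_filter = [chain_filter]

    rows = []
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            rname = res.name.strip().upper()
            if rname not in KNOWN_RESIDUES:
                if rname == "HOH":
                    continue
                if strict_unknown:
                    raise UnknownResidueError(
                        f"unknown residue {rname} at {chain.name}/{res.seqid.num}")
                log.warning("skipping unknown residue %s %s/%s", rname,
                            chain.name, res.seqid.num)
                continue
            # altloc resolution: per atom name, highest occupancy then 'A'
            by_name: dict[str, list] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, copies in by_name.items():
                atom = min(copies, key=lambda a: (-a.occ, a.altloc or "A"))
                el = atom.element.name.upper() if atom.element else ""
                if el not in _SUPPORTED_ELEMENTS:
                    try:
                        el = topo.element_of(name)
                    except ValueError:
                        continue
                    if el not in _SUPPORTED_ELEMENTS:
                        continue
                rows.append((chain.name, res.seqid.num,
                             (res.seqid.icode or "").strip(), rname, name, el,
                             np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                             atom.occ, atom.b_iso))
    if not rows:
        raise PDBParseError(f"no recognizable protein atoms in {path}")
    return structure_from_atoms(rows, source=str(path))


def pose_from_structure(structure: TargetStructure, chain: str | None = None,
                        cyclic: bool | None = None) -> PeptidePose:
    """Reconstruct a PeptidePose from one chain of a structure.

    ``cyclic=None`` auto-detects a head-to-tail bond from the C(last)–N(first)
    distance (< 1.7 Å).
    """
    if chain is None:
        chains = structure.chains()
        if len(chains) != 1:
            raise ResidueLookupError("chain must be named for multi-chain input")
        chain = chains[0]
    sub = structure.select_chains(chain)
    residues = []
    for _, _, _, rname, idx in sub.iter_residues():
        t = topo.get_topology(rname)
        atoms = {str(sub.names[i]): sub.coords[i].copy() for i in idx}
        residues.append(Residue(t, atoms))
    if not residues:
        raise ResidueLookupError(f"no residues in chain {chain}")
    if cyclic is None:
        try:
            d = np.linalg.norm(residues[-1].atoms["C"] - residues[0].atoms["N"])
            cyclic = bool(d < 1.7) and len(residues) > 2
        except KeyError:
            cyclic = False
    return PeptidePose(residues, cyclic=cyclic)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(serial, name, resname, chain, resseq, icode, xyz, occ, bfac, element):
    return (
        f"ATOM  {serial:>5d} {_format_atom_name(name, element)} "
        f"{resname:>3s} {chain:1s}{resseq:>4d}{icode:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{bfac:6.2f}"
        f"          {element:>2s}  \n"
    )


def _link_line(name1, res1, chain1, seq1, name2, res2, chain2, seq2, dist):
    return (
        f"LINK        {_format_atom_name(name1, name1[0])} {res1:>3s} {chain1:1s}"
        f"{seq1:>4d}                {_format_atom_name(name2, name2[0])} "
        f"{res2:>3s} {chain2:1s}{seq2:>4d}     1555   1555 {dist:5.2f}\n"
    )


def write_pdb(path, pose: PeptidePose | None = None,
              target: TargetStructure | None = None,
              pose_chain: str = "P") -> None:
    """Write a pose, a target, or a pose+target complex as PDB v3.3.

    A cyclic pose gets one LINK record connecting the last residue's C to the
    first residue's N.  D residues are written with their 3-letter CCD codes.
    """
    if pose is None and target is None:
        raise ValueError("nothing to write")
    lines: list[str] = []
    if pose is not None and pose.cyclic:
        first = pose.residues[0]
        last = pose.residues[-1]
        dist = float(np.linalg.norm(last.atoms["C"] - first.atoms["N"]))
        lines.append(_link_line("C", last.identity, pose_chain, len(pose),
                                "N", first.identity, pose_chain, 1, dist))
    serial = 1
    if target is not None:
        current_chain = None
        for i in range(target.n_atoms):
            ch = str(target.chain_ids[i])
            if current_chain is not None and ch != current_chain:
                lines.append("TER\n")
            current_chain = ch
            lines.append(_atom_line(
                serial, str(target.names[i]), str(target.resnames[i]), ch,
                int(target.resseqs[i]), str(target.icodes[i]) or " ",
                target.coords[i], float(target.occupancies[i]),
                float(target.b_factors[i]), str(target.elements[i])))
            serial += 1
        lines.append("TER\n")
    if pose is not None:
        for i, r in enumerate(pose.residues):
            for name in _pose_atom_order(r):
                el = topo.element_of(name)
                lines.append(_atom_line(serial, name, r.identity, pose_chain,
                                        i + 1, " ", r.atoms[name], 1.0, 0.0, el))
                serial += 1
        lines.append("TER\n")
    lines.append("END\n")
    try:
        with open(path, "w") as fh:
            fh.writelines(lines)
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc


def fetch_pdb(accession: str, dest_dir: str = ".") -> str:
    """Download an entry from the PDB (network helper; never used by the
    core design path or the test suite)."""
    import urllib.request

    url = f"https://files.rcsb.org/download/{accession.upper()}.pdb"
    dest = os.path.join(dest_dir, f"{accession.upper()}.pdb")
    urllib.request.urlretrieve(url, dest)  # noqa: S310
    return dest
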