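"""Compact canonical side-chain rotamer library.

Each rotatable sp³ bond samples χ ∈ {−60°, 60°, 180°}; the terminal torsion
of the flat aromatic rings (Phe/Tyr/Trp/His χ₂) samples {−90°, 90°}.
D rotamers are the exact sign mirrors of the L entries.  Pro (rigid ring)
and Gly/Ala (no rotatable χ) have a single empty rotamer.
"""

from __future__ import annotations

from itertools import product

from . import topology as topo

_SP3 = (-60.0, 60.0, 180.0)
_RING = (-90.0, 90.0)
_RING_CHI2 = {"PHE", "TYR", "TRP", "HIS"}


def rotamer_set(identity: str) -> list[tuple[float, ...]]:
    """All canonical χ combinations for an identity (3-letter code)."""
    t = topo.get_topology(identity)
    if t.n_chi == 0:
        return [()]
    parent = topo.D_CODES.get(t.name3, t.name3)
    choices = []
    for k in range(1, t.n_chi + 1):
        if k == 2 and parent in _RING_CHI2:
            choices.append(_RING)
        else:
            choices.append(_SP3)
    combos = [tuple(c) for c in product(*choices)]
    if t.chirality == "D":
        combos = [tuple(-x for x in c) for c in combos]
    return combos


def scan_rotamer_set(identity: str, offset_step: float = 20.0) -> list[tuple[float, ...]]:
    """Rotamer set for hotspot placement scans: every canonical combination
    plus ±``offset_step`` sub-samples around each χ."""
    base = rotamer_set(identity)
    if base == [()]:
        return base
    offsets = (-offset_step, 0.0, offset_step)
    out = []
    seen = set()
    for combo in base:
        for off in product(offsets, repeat=len(combo)):
            chis = tuple(topo_wrap(c + o) for c, o in zip(combo, off))
            if chis not in seen:
                seen.add(chis)
                out.append(chis)
    return out


def topo_wrap(a: float) -> float:
    w = (a + 180.0) % 360.0 - 180.0
    return w + 360.0 if w <= -180.0 else w
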