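"""Shared toy design problem: 2 designable positions × 3 identity choices."""

import itertools

from macpep import topology as topo
from macpep.design import (DesignPalette, MCSchedule, _DesignContext, design,
                           position_chiralities)
from macpep.energy import DEFAULT_PARAMS
from macpep.geometry import TorsionSet, build_chain

PALETTE = DesignPalette(identities=("SER", "VAL", "LEU"), allow_gly=False)
LIBRARY = {
    "SER": [(-60.0,)], "DSN": [(60.0,)],
    "VAL": [(180.0,)], "DVA": [(180.0,)],
    "LEU": [(-60.0, 180.0)], "DLE": [(60.0, 180.0)],
}


def two_position_pose(anchor):
    """Anchor residue plus two designable Gly positions hovering over the
    target surface."""
    tors = [TorsionSet(-120.0, 130.0, 180.0, ()),
            TorsionSet(-70.0, -40.0, 180.0, ()),
            TorsionSet(-70.0, -40.0, 180.0, ())]
    return build_chain([anchor.identity, "GLY", "GLY"], tors,
                       anchor={k: anchor.atoms[k] for k in ("N", "CA", "C")},
                       anchor_index=0, anchor_all_atoms=anchor.copy_atoms())


def enumeration_optimum(pose, ctx):
    """Brute force over all 3×3 sequence states using direct evaluation of
    the design objective (independent of the MC trajectory)."""
    chir = position_chiralities(pose)
    designable = [1, 2]
    dctx = _DesignContext(pose.copy(), ctx, DEFAULT_PARAMS)
    anchor_sc = {e.name: pose.residues[0].atoms[e.name]
                 for e in pose.residues[0].topology.sidechain
                 if e.name in pose.residues[0].atoms}
    results = []
    for combo in itertools.product(PALETTE.codes_for(chir[1]),
                                   PALETTE.codes_for(chir[2])):
        sidechains = {0: anchor_sc}
        for pos, ident in zip(designable, combo):
            sidechains[pos] = dctx.sidechain_atoms(pos, ident,
                                                   LIBRARY[ident][0])
        # each inter-position pair counted exactly once: position 1 sees
        # position 2's side chain, position 2 only the fixed anchor
        e1 = dctx.local_energy(1, combo[0], LIBRARY[combo[0]][0], sidechains)
        e2 = dctx.local_energy(2, combo[1], LIBRARY[combo[1]][0],
                               {0: anchor_sc, 2: sidechains[2]})
        results.append((e1 + e2, combo))
    results.sort()
    return results[0][1]


def mc_optimum(pose, ctx, seed, moves=600):
    rec = design(pose, ctx, palette=PALETTE, library=LIBRARY,
                 schedule=MCSchedule(moves=moves, seed=seed),
                 compute_report=False, refine=False)
    return tuple(rec.sequence[1:3])
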