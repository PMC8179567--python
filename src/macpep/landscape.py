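"""Sequence-specific conformational energy landscapes.

For a designed macrocycle (fixed sequence and per-position chirality), closed
conformers are sampled *without* the target by kinematic closure with
chirality-matched Ramachandran bins, side chains are repacked with the
identities fixed, and each relaxed conformer is scored and compared to the
design by backbone RMSD.  A design is considered pre-organized (a "funnel")
when the lowest-energy sample lies within a cutoff (default 1 Å) of the
designed conformation.  The design conformation itself is always injected as
sample 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import topology as topo
from .closure import _sample_ring
from .design import _DesignContext, metropolis_accept, position_chiralities
from .energy import DEFAULT_PARAMS, ScoreParams, score
from .exceptions import InsufficientSamplesError, ParameterError
from .geometry import PeptidePose, pose_rmsd
from .rama import bins_for_chirality, default_bins
from .rotamers import rotamer_set

log = logging.getLogger(__name__)


@dataclass
class FunnelPoint:
    sample_id: int
    energy: float
    rmsd: float  # Å to the designed conformation


@dataclass
class LandscapeVerdict:
    lowest_energy_rmsd: float
    low_energy_median_rmsd: float  # median RMSD of the lowest-5%-energy samples
    passed: bool
    cutoff: float


def _repack(pose: PeptidePose, params: ScoreParams, rng: np.random.Generator,
            moves_per_position: int = 8) -> PeptidePose:
    """Light rotamer-only Monte-Carlo repack (identities fixed)."""
    packable = [i for i in range(len(pose))
                if pose.residues[i].topology.n_chi > 0]
    if not packable:
        return pose
    pose = pose.copy()
    dctx = _DesignContext(pose, None, params)
    identities = [r.identity for r in pose.residues]
    libs = {i: rotamer_set(identities[i]) for i in packable}
    chis = {i: libs[i][0] for i in packable}
    sidechains = {i: dctx.sidechain_atoms(i, identities[i], chis[i])
                  for i in packable}
    locals_ = {i: dctx.local_energy(i, identities[i], chis[i], sidechains)
               for i in packable}
    n_moves = moves_per_position * len(packable)
    temps = np.geomspace(1.0, 0.1, n_moves)
    for T in temps:
        i = packable[int(rng.integers(len(packable)))]
        cand = libs[i][int(rng.integers(len(libs[i])))]
        saved = (chis[i], sidechains[i], locals_[i])
        chis[i] = cand
        sidechains[i] = dctx.sidechain_atoms(i, identities[i], cand)
        e_new = dctx.local_energy(i, identities[i], cand, sidechains)
        if metropolis_accept(e_new - saved[2], float(T), rng):
            locals_[i] = e_new
        else:
            chis[i], sidechains[i], locals_[i] = saved
    from .geometry import Residue, build_sidechain

    for i in packable:
        r = pose.residues[i]
        keep = {k: r.atoms[k] for k in ("N", "CA", "C", "O", "H") if k in r.atoms}
        build_sidechain(keep, r.topology, chis[i])
        pose.residues[i] = Residue(r.topology, keep)
    return pose


def predict_landscape(design, n_samples: int, seed: int = 0,
                      params: ScoreParams = DEFAULT_PARAMS, bins=None,
                      rmsd_selection: str = "backbone-heavy",
                      max_attempt_factor: int = 10) -> list[FunnelPoint]:
    """Sample the conformational landscape of a designed sequence.

    ``design`` is a DesignRecord or a cyclic PeptidePose.  Every sample is a
    closed ring honoring the design's per-position chirality bins, repacked
    and scored without the target.  Sample 0 is the design itself.
    """
    pose = design.pose if hasattr(design, "pose") else design
    if n_samples <= 0:
        raise ParameterError("n_samples must be positive")
    if not pose.cyclic:
        raise ParameterError("landscape prediction needs a cyclic pose")
    n = len(pose)
    all_bins = bins if bins is not None else default_bins()
    chir = position_chiralities(pose)
    per_pos = [bins_for_chirality(all_bins, c) or all_bins for c in chir]

    points = [FunnelPoint(0, score(pose, None, params, bins=bins).total, 0.0)]
    attempt_block = 0
    max_attempts = max_attempt_factor * n_samples
    attempts_done = 0
    # root frame only: O/H/side chain of residue 0 are rebuilt per sample
    anchor_atoms = {k: pose.residues[0].atoms[k] for k in ("N", "CA", "C")}
    topologies = [r.topology for r in pose.residues]
    while len(points) <= n_samples and attempts_done < max_attempts:
        block = min(64, max_attempts - attempts_done)
        sols = _sample_ring(topologies, anchor_atoms, 0, block, all_bins,
                            seed=np.random.SeedSequence(
                                [int(seed), attempt_block]).generate_state(1)[0]
                            % (2 ** 31),
                            target_ctx=None, params=params,
                            score_against_target=False,
                            per_position_bins=per_pos, grid=360)
        attempts_done += block
        attempt_block += 1
        for k, sol in enumerate(sols):
            if len(points) > n_samples:
                break
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), attempt_block, k]))
            relaxed = _repack(sol.pose, params, rng)
            e = score(relaxed, None, params, bins=bins).total
            rmsd = pose_rmsd(relaxed, pose, rmsd_selection)
            points.append(FunnelPoint(len(points), e, rmsd))
    log.info("landscape: %d points from %d attempts", len(points), attempts_done)
    return points


def funnel_verdict(points: list[FunnelPoint], cutoff: float = 1.0) -> LandscapeVerdict:
    """Pre-organization verdict: pass iff the minimum-energy sample's RMSD to
    the design is below the cutoff."""
    if len(points) < 10:
        raise InsufficientSamplesError("need at least 10 landscape points")
    energies = np.array([p.energy for p in points])
    rmsds = np.array([p.rmsd for p in points])
    imin = int(np.argmin(energies))
    k = max(1, int(np.ceil(0.05 * len(points))))
    low_idx = np.argsort(energies)[:k]
    return LandscapeVerdict(
        lowest_energy_rmsd=float(rmsds[imin]),
        low_energy_median_rmsd=float(np.median(rmsds[low_idx])),
        passed=bool(rmsds[imin] < cutoff),
        cutoff=float(cutoff),
    )


def write_funnel_tsv(points: list[FunnelPoint], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tenergy\trmsd\n")
        for p in points:
            fh.write(f"{p.sample_id}\t{p.energy:.6f}\t{p.rmsd:.6f}\n")


def plot_funnel(points: list[FunnelPoint], path, cutoff: float = 1.0) -> None:
    """Energy-vs-RMSD scatter (optional diagnostic figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rmsds = [p.rmsd for p in points]
    energies = [p.energy for p in points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(rmsds[1:], energies[1:], s=8, alpha=0.6, label="samples")
    ax.scatter(rmsds[:1], energies[:1], s=40, color="crimson", label="design")
    ax.axvline(cutoff, ls="--", lw=1, color="grey")
    ax.set_xlabel("backbone RMSD to design (Å)")
    ax.set_ylabel("energy (arb. units)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
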