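"""End-to-end design protocol: anchor → poly-Gly extension → kinematic
backbone sampling → energy/H-bond filter cascade → sequence design →
interface metrics → ranking (→ optional landscape validation).

Every stage is seeded deterministically from the run seed, per-stage
candidate counts are logged and returned, and all outputs (scorefile,
design PDBs, run config, counters) land in the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .closure import ClosureSolution, sample_closed_backbones
from .design import (DesignPalette, DesignRecord, MCSchedule, design,
                     rank_designs)
from .energy import (DEFAULT_PARAMS, ScoreParams, TargetContext,
                     count_backbone_hbonds)
from .exceptions import ConfigurationError, ParameterError
from .hotspot import extract_hotspot, rotamer_scan_place, extend_polygly
from .landscape import funnel_verdict, predict_landscape, write_funnel_tsv
from .pdbio import read_pdb, write_pdb

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """The filter cascade applied to scored closure solutions."""

    max_energy: float = 0.0          # discard E > max_energy
    min_backbone_hbonds: int = 2     # discard rings with fewer backbone H-bonds
    clash_frac: float = 0.6
    keep_top_k: int = 10             # after ranking

    def __post_init__(self):
        if self.keep_top_k < 1:
            raise ConfigurationError("keep_top_k must be at least 1")


@dataclass
class DesignSpec:
    """Everything needed to reproduce one design run."""

    target_path: str = ""
    hotspot_mode: str = "extract"    # "extract" | "scan"
    partner_chain: str = ""
    partner_res: int = 0
    hotspot_identity: str = "TRP"
    site: tuple[float, float, float] | None = None
    normal: tuple[float, float, float] | None = None
    spin: float = 0.0
    target_chains: tuple[str, ...] = ()
    ring_sizes: tuple[int, ...] = (8, 9, 10)
    n_attempts: int = 10000
    seed: int = 1
    out_dir: str = "macpep_out"
    max_designs_per_size: int = 6
    landscape_top_k: int = 0
    landscape_samples: int = 2000
    filters: FilterConfig = field(default_factory=FilterConfig)
    mc_moves: int = 5000
    mc_t_start: float = 3.0
    mc_t_end: float = 0.3
    mc_stages: int = 10
    palette: tuple[str, ...] = DesignPalette().identities

    def __post_init__(self):
        for n in self.ring_sizes:
            if not 7 <= int(n) <= 12:
                raise ParameterError("ring sizes must be within [7, 12]")


# -- TOML round-trip --------------------------------------------------------


def spec_to_toml(spec: DesignSpec) -> str:
    def fmt(v):
        if isinstance(v, (bool, np.bool_)):
            return "true" if v else "false"
        if isinstance(v, (int, np.integer)):
            return repr(int(v))
        if isinstance(v, (float, np.floating)):
            return repr(float(v))
        if isinstance(v, str):
            return json.dumps(v)
        if isinstance(v, (tuple, list)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(f"cannot serialize {v!r}")

    lines = ["[design]"]
    for f in dataclasses.fields(spec):
        v = getattr(spec, f.name)
        if f.name == "filters" or v is None:
            continue
        lines.append(f"{f.name} = {fmt(v)}")
    lines.append("")
    lines.append("[filters]")
    for f in dataclasses.fields(spec.filters):
        lines.append(f"{f.name} = {fmt(getattr(spec.filters, f.name))}")
    return "\n".join(lines) + "\n"


def spec_from_toml(text: str) -> DesignSpec:
    import tomllib

    data = tomllib.loads(text)
    d = dict(data.get("design", {}))
    filt = FilterConfig(**data.get("filters", {}))
    for key in ("ring_sizes", "palette", "target_chains", "site", "normal"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    d.pop("filters", None)
    return DesignSpec(filters=filt, **d)


# -- filter cascade ---------------------------------------------------------


def apply_filters(solutions: list[ClosureSolution], cfg: FilterConfig,
                  params: ScoreParams = DEFAULT_PARAMS) -> list[ClosureSolution]:
    """Keep solutions with E ≤ max_energy (boundary kept) and at least
    ``min_backbone_hbonds`` intramolecular backbone hydrogen bonds; order
    preserved."""
    out = []
    for sol in solutions:
        if sol.energy is None or sol.energy.total > cfg.max_energy:
            continue
        if count_backbone_hbonds(sol.pose, params) < cfg.min_backbone_hbonds:
            continue
        out.append(sol)
    return out


# -- run orchestration ------------------------------------------------------


@dataclass
class RunResult:
    records: list[DesignRecord]
    stage_counts: dict
    out_dir: str
    scorefile: str


_SCORE_COLUMNS = ["design_id", "ring_size", "sequence", "total_E", "steric",
                  "hbond", "rama", "composition", "interaction_energy",
                  "buried_sasa", "sc", "inter_hbonds", "intra_hbonds", "pdb"]


def _derived_seed(seed: int, *keys) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, keys)])
               .generate_state(1)[0] % (2 ** 31))


def _resolve_anchor(spec: DesignSpec, target):
    if spec.hotspot_mode == "extract":
        anchor, target = extract_hotspot(target, spec.partner_chain,
                                         spec.partner_res)
        return anchor, target
    if spec.hotspot_mode == "scan":
        if spec.site is None or spec.normal is None:
            raise ConfigurationError("scan mode needs an explicit site and normal")
        anchor, _ = rotamer_scan_place(target, spec.hotspot_identity,
                                       np.asarray(spec.site, float),
                                       np.asarray(spec.normal, float),
                                       spec.spin)
        return anchor, target
    raise ConfigurationError(f"unknown hotspot mode {spec.hotspot_mode!r}")


def run_design(spec: DesignSpec, target=None) -> RunResult:
    """Execute the full protocol; fully reproducible under ``spec.seed``."""
    os.makedirs(spec.out_dir, exist_ok=True)
    os.makedirs(os.path.join(spec.out_dir, "designs"), exist_ok=True)
    log_path = os.path.join(spec.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("macpep")
    root.addHandler(handler)
    try:
        return _run(spec, target)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(spec: DesignSpec, target) -> RunResult:
    if target is None:
        target = read_pdb(spec.target_path,
                          chain_filter=list(spec.target_chains) or None)
    anchor, target = _resolve_anchor(spec, target)
    ctx = TargetContext(target)
    palette = DesignPalette(identities=tuple(spec.palette))
    counts: dict = {"per_ring": {}, "total_designed": 0, "total_ranked": 0}
    records: list[DesignRecord] = []

    for n in spec.ring_sizes:
        n = int(n)
        n_nterm = (n - 1) // 2
        n_cterm = n - 1 - n_nterm
        pose = extend_polygly(anchor, n_nterm, n_cterm)
        stats: dict = {}
        sols = sample_closed_backbones(
            pose, ctx, spec.n_attempts, seed=_derived_seed(spec.seed, n),
            stats=stats)
        e_pass = [s for s in sols
                  if s.energy is not None
                  and s.energy.total <= spec.filters.max_energy]
        survivors = apply_filters(sols, spec.filters)
        survivors.sort(key=lambda s: s.energy.total)
        picked = survivors[:spec.max_designs_per_size]
        ring_counts = {
            "attempts": stats.get("attempts", spec.n_attempts),
            "closed": stats.get("closed", 0),
            "clash_rejected": stats.get("clash_rejected", 0),
            "scored": stats.get("kept", 0),
            "energy_filter_pass": len(e_pass),
            "hbond_filter_pass": len(survivors),
            "designed": len(picked),
        }
        counts["per_ring"][str(n)] = ring_counts
        log.info("ring %d: %s", n, ring_counts)
        for j, sol in enumerate(picked):
            schedule = MCSchedule(moves=spec.mc_moves, t_start=spec.mc_t_start,
                                  t_end=spec.mc_t_end, stages=spec.mc_stages,
                                  seed=_derived_seed(spec.seed, n, j))
            rec = design(sol.pose, ctx, palette=palette, schedule=schedule)
            rec.design_id = f"r{n}_c{j:03d}"
            rec.source_energy = sol.energy.total
            rec.source_backbone_hbonds = count_backbone_hbonds(sol.pose)
            records.append(rec)

    counts["total_designed"] = len(records)
    ranked = rank_designs(records) if records else []
    ranked = ranked[:spec.filters.keep_top_k]
    counts["total_ranked"] = len(ranked)
    if not ranked:
        log.warning("no designs survived the filter cascade")

    scorefile = os.path.join(spec.out_dir, "scorefile.tsv")
    with open(scorefile, "w") as fh:
        fh.write("\t".join(_SCORE_COLUMNS) + "\n")
        for rank, rec in enumerate(ranked, start=1):
            pdb_name = f"designs/design_{rank:03d}_{rec.design_id}.pdb"
            write_pdb(os.path.join(spec.out_dir, pdb_name), pose=rec.pose,
                      target=target)
            rep = rec.report
            row = [f"{rec.design_id}", str(rec.ring_size),
                   rec.sequence_string(),
                   f"{rec.energy.total:.4f}", f"{rec.energy.steric:.4f}",
                   f"{rec.energy.hbond:.4f}", f"{rec.energy.rama:.4f}",
                   f"{rec.energy.composition:.4f}",
                   f"{rep.interaction_energy:.4f}", f"{rep.buried_sasa:.2f}",
                   f"{rep.sc:.4f}", str(rep.inter_hbond_count),
                   str(rep.intra_hbond_count), pdb_name]
            fh.write("\t".join(row) + "\n")

    with open(os.path.join(spec.out_dir, "run_config.toml"), "w") as fh:
        fh.write(spec_to_toml(spec))
    with open(os.path.join(spec.out_dir, "stage_counts.json"), "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)

    if spec.landscape_top_k > 0:
        for rank, rec in enumerate(ranked[:spec.landscape_top_k], start=1):
            pts = predict_landscape(rec, spec.landscape_samples,
                                    seed=_derived_seed(spec.seed, 99, rank))
            write_funnel_tsv(pts, os.path.join(
                spec.out_dir, f"funnel_{rank:03d}_{rec.design_id}.tsv"))
            verdict = funnel_verdict(pts)
            with open(os.path.join(
                    spec.out_dir, f"funnel_{rank:03d}_{rec.design_id}.json"),
                    "w") as fh:
                json.dump(dataclasses.asdict(verdict), fh, indent=2)

    return RunResult(records=ranked, stage_counts=counts,
                     out_dir=spec.out_dir, scorefile=scorefile)
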