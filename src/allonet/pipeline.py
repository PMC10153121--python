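"""End-to-end analysis orchestration from a single YAML config.

Stages, in order, per trajectory: load -> backbone RMSD -> equilibration
pruning -> decorrelation -> state classification -> interaction detection
(+ ligand site/retention analysis for ligand-bound members); then across
the ensemble: occupancy aggregation, the five-step h-bond network
isolation, interface-disruption reports, and a deterministic summary
JSON. Every stage's output is written under the output directory, stamped
with a hash of the configuration, so any downstream stage can be resumed
from disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import interactions as ia
from . import ligand as lg
from . import network as nw
from . import prep, states
from .regions import RegionMap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "TrajectoryEntry", "validate_config", "run_pipeline",
           "PipelineError"]

VALID_LABELS = (nw.APO_OPEN, nw.APO_CLOSED)   # plus "ligand:<name>"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, trajectory: str | None, cause: Exception):
        self.stage = stage
        self.trajectory = trajectory
        where = f" for trajectory {trajectory!r}" if trajectory else ""
        super().__init__(f"stage {stage!r} failed{where}: {cause}")


@dataclass
class TrajectoryEntry:
    name: str
    coords: str
    topology: str
    label: str


@dataclass
class RunConfig:
    trajectories: list[TrajectoryEntry]
    regions: str                              # path to regions.yaml
    state: states.StateConfig
    hbond: ia.HbondCriteria = field(default_factory=ia.HbondCriteria)
    network: nw.NetworkConfig = field(default_factory=nw.NetworkConfig)
    min_beta_sheets: int = 2
    site_precedence: tuple[str, ...] = (lg.ALPHA, lg.BETA)
    contact_cutoff: float = 4.0
    grace_frames: int = 0
    dissociation_window: int = 10
    n_boot: int = 1000
    outdir: str = "allonet_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        base = Path(path).parent

        def _resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        trajs = [TrajectoryEntry(name=t["name"], coords=_resolve(t["coords"]),
                                 topology=_resolve(t["topology"]),
                                 label=t["label"])
                 for t in d["trajectories"]]
        return cls(
            trajectories=trajs,
            regions=_resolve(d["regions"]),
            state=states.StateConfig(**d["state"]),
            hbond=ia.HbondCriteria(**d.get("hbond", {})),
            network=nw.NetworkConfig(**d.get("network", {})),
            min_beta_sheets=d.get("min_beta_sheets", 2),
            site_precedence=tuple(d.get("site_precedence",
                                        (lg.ALPHA, lg.BETA))),
            contact_cutoff=d.get("contact_cutoff", 4.0),
            grace_frames=d.get("grace_frames", 0),
            dissociation_window=d.get("dissociation_window", 10),
            n_boot=d.get("n_boot", 1000),
            outdir=str(d.get("outdir", "allonet_out")),
            seed=int(d.get("seed", 0)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_config(cfg: RunConfig) -> list[str]:
    """Check all config invariants; returns every violation found."""
    errors: list[str] = []
    if not cfg.trajectories:
        errors.append("no trajectories in manifest")
    names = [t.name for t in cfg.trajectories]
    if len(set(names)) != len(names):
        errors.append("duplicate trajectory names in manifest")
    for t in cfg.trajectories:
        for p, what in ((t.coords, "coords"), (t.topology, "topology")):
            if not Path(p).exists():
                errors.append(f"{t.name}: {what} file not found: {p}")
        if t.label not in VALID_LABELS and not t.label.startswith("ligand:"):
            errors.append(f"{t.name}: label {t.label!r} not in "
                          f"{VALID_LABELS} or 'ligand:<name>'")
    if not Path(cfg.regions).exists():
        errors.append(f"regions file not found: {cfg.regions}")
    else:
        try:
            RegionMap.from_yaml(cfg.regions)
        except Exception as e:  # surfaced as config error, not a crash
            errors.append(f"regions file invalid: {e}")
    if cfg.n_boot < 1:
        errors.append("n_boot must be >= 1")
    if cfg.min_beta_sheets not in (1, 2, 3):
        errors.append("min_beta_sheets must be 1, 2 or 3")
    return errors


def _stage(stage: str, trajectory: str | None = None):
    """Context manager converting stage exceptions to PipelineError."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, trajectory, exc) from exc
            return False
    return _Ctx()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the report bundle; returns the summary
    dict (which is also written as ``summary.json``, byte-deterministic
    for a fixed config + seed)."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"- {e}" for e in errors))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    regions = RegionMap.from_yaml(cfg.regions)
    sites = lg.default_sites(cfg.min_beta_sheets)
    summary: dict = {"config_hash": chash, "seed": cfg.seed,
                     "trajectories": {}, "network": {}, "interfaces": {}}

    hb_results: dict[str, ia.DetectionResult] = {}
    ct_results: dict[str, ia.DetectionResult] = {}
    selections: dict[str, list[int]] = {}
    labels = {t.name: t.label for t in cfg.trajectories}
    contact_scope = list(nw.DEFAULT_INTERFACES)

    for entry in cfg.trajectories:
        name = entry.name
        with _stage("load", name):
            traj = prep.load_trajectory(entry.coords, entry.topology)
            problems = regions.validate_against(traj.topology)
            if problems:
                raise ValueError("; ".join(problems))
        with _stage("prep", name):
            rmsd = prep.backbone_rmsd_series(traj)
            start = prep.detect_equilibration(rmsd)
            sel = prep.decorrelate(rmsd, start)
            sel.to_json(outdir / f"{name}.selection.json")
            selections[name] = sel.frames
        with _stage("states", name):
            table = states.state_table(traj, regions, cfg.state)
            table.to_csv(outdir / f"{name}.states.tsv", sep="\t", index=False)
            retained = table.iloc[sel.frames] if sel.frames else table
            wpd_majority = retained["wpd_state"].mode().iloc[0]
            _, a7_label = states.classify_alpha7(
                retained["helicity_pct"].to_numpy(), cfg.state)
        with _stage("interactions", name):
            hb_results[name] = ia.detect_hbonds(traj, cfg.hbond)
            has_ligand = ia.ligand_residue_index(traj.topology) is not None
            scope = contact_scope + ([(r, ia.LIGAND) for r in
                                      regions.regions] if has_ligand else [])
            ct_results[name] = ia.residue_contacts(traj, regions, scope,
                                                   cfg.contact_cutoff)
        traj_summary = {
            "label": entry.label, "n_frames": int(traj.n_frames),
            "equil_start": int(sel.equil_start),
            "n_retained": len(sel.frames),
            "wpd_majority": wpd_majority, "a7_state": a7_label,
        }
        if has_ligand:
            with _stage("ligand", name):
                trace = lg.classify_site(traj, regions, sites,
                                         cfg.contact_cutoff,
                                         cfg.site_precedence)
                _, any_contact = lg.ligand_region_contacts(
                    traj, regions, cfg.contact_cutoff)
                for site in (lg.ALPHA, lg.BETA):
                    trace.retention_ns[site] = lg.retention_time(
                        trace.labels, trace.dt, site, cfg.grace_frames)
                trace.dissociation_ns = lg.detect_dissociation(
                    traj, regions, cfg.contact_cutoff,
                    cfg.dissociation_window, any_contact=any_contact)
                # COM RMSD over the bound portion of the retained frames
                retained_frames = sel.frames or list(range(traj.n_frames))
                bound = [f for f in retained_frames if any_contact[f]]
                com = lg.ligand_com_rmsd(traj, bound or retained_frames,
                                         n_boot=cfg.n_boot, seed=cfg.seed)
                _write_site_trace(outdir / f"{name}.sites.tsv", trace)
                traj_summary["ligand"] = {
                    "retention_ns": {k: round(v, 6)
                                     for k, v in trace.retention_ns.items()},
                    "dissociation_ns": trace.dissociation_ns,
                    "com_rmsd_mean_A": round(com.mean, 6),
                    "com_rmsd_se_A": round(com.se, 6),
                    "n_boot": com.n_boot,
                }
        summary["trajectories"][name] = traj_summary

    with _stage("occupancy", None):
        hb_table = ia.occupancy(hb_results, selections, labels)
        hb_table.to_tsv(outdir / "hbond_occupancy.tsv",
                        outdir / "ensemble_labels.json")
        ct_table = ia.occupancy(ct_results, selections, labels)
        ct_table.to_tsv(outdir / "contact_occupancy.tsv")

    with _stage("network", None):
        filtered = nw.filter_adjacent(nw.filter_ubiquitous(hb_table,
                                                           cfg.network),
                                      cfg.network)
        result = nw.assign_state_bonds(filtered, cfg.network)
        result = nw.build_graph(result, regions, state="closed-network")
        result.bonds.to_csv(outdir / "network_bonds.tsv", sep="\t",
                            index_label="bond")
        bond_records = {k: {c: (row[c] if isinstance(row[c], str)
                                else float(row[c]))
                            for c in result.bonds.columns}
                        for k, row in result.bonds.iterrows()}
        (outdir / "network_bonds.json").write_text(
            json.dumps(bond_records, sort_keys=True, indent=1))
        edges = [{"bond": k,
                  "a": result.records[k].a, "b": result.records[k].b}
                 for k in result.assigned("closed-network")
                 + result.assigned("open-network")]
        with open(outdir / "network_edges.tsv", "w") as fh:
            fh.write("bond\ta\tb\n")
            for e in edges:
                fh.write(f"{e['bond']}\t{e['a']}\t{e['b']}\n")
        summary["network"] = {
            "n_candidate_bonds": int(len(hb_table.data)),
            "n_after_filters": int(len(filtered.data)),
            "closed_network": sorted(result.assigned("closed-network")),
            "open_network": sorted(result.assigned("open-network")),
            "active_to_allosteric_connected": bool(result.connected),
        }

    with _stage("interfaces", None):
        iface_rows = []
        for iface in nw.DEFAULT_INTERFACES:
            rep = nw.interface_disruption(ct_table, regions, iface,
                                          cfg.network, strict_groups=False)
            iface_rows.append({"interface": "-".join(iface),
                               **{f"n_{k}": v for k, v in rep.counts.items()},
                               "pct_diff_closed_over_open":
                                   round(rep.percent_difference, 4),
                               "n_disrupted": len(rep.disrupted)})
            summary["interfaces"]["-".join(iface)] = {
                "counts": rep.counts,
                "percent_difference_closed_over_open":
                    round(rep.percent_difference, 6),
                "percent_difference_undefined": rep.undefined_percent,
                "n_disrupted": int(len(rep.disrupted)),
                "disrupted": sorted(rep.disrupted["interaction"].tolist()),
            }
        import pandas as pd
        pd.DataFrame(iface_rows).to_csv(outdir / "interfaces.tsv",
                                        sep="\t", index=False)

    blob = json.dumps(summary, sort_keys=True, indent=1, default=_jsonify)
    (outdir / "summary.json").write_text(blob)
    logger.info("pipeline complete; %d trajectories, config %s",
                len(cfg.trajectories), chash)
    return summary


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _write_site_trace(path, trace: lg.SiteTrace) -> None:
    with open(path, "w") as fh:
        fh.write("frame\ttime_ns\tlabel\n")
        for f, lab in enumerate(trace.labels):
            fh.write(f"{f}\t{f * trace.dt:.6f}\t{lab}\n")
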