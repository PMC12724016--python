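"""Configuration-driven orchestration of every analysis stage.

A study config (YAML) names systems (topology, parameter table, replica
trajectories), named selections, and per-stage parameters.  ``run_study``
restricts each replica to its analysis window (by default the last half of
frames), superposes, and runs the enabled stages, writing one CSV per stage
per system plus a run manifest.  All outputs are deterministic for a fixed
config and inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .essential import average_dccm, compute_dccm, compute_pca, pc_loadings
from .exceptions import ConfigError, InputError
from .gbsa import EnergyOptions, binding_free_energy, per_residue_decomposition
from .interface import distance_series, scan_interface_salt_bridges, site_sasa
from .network import build_network, export_edges, optimal_path, path_report
from .trajio import (
    concatenate,
    read_parameters,
    read_structure,
    read_trajectory,
    select,
    superpose,
)

__all__ = [
    "StudyConfig",
    "ReplicaAggregate",
    "load_config",
    "run_study",
    "aggregate_replicas",
    "compare_systems",
    "percent_of_reference",
]

logger = logging.getLogger(__name__)

_STAGE_DEFAULTS: dict[str, dict] = {
    "pca": {"enabled": False, "selection": "name CA", "components": 2},
    "dccm": {"enabled": False, "selection": "name CA"},
    "network": {
        "enabled": False,
        "selection": "name CA",
        "contact_cutoff": 4.5,
        "occupancy_threshold": 0.75,
        "neighbor_exclusion": 1,
        "paths": [],
    },
    "saltbridges": {
        "enabled": False,
        "selection_a": "",
        "selection_b": "",
        "cutoff": 4.0,
        "min_population": 0.0,
    },
    "distances": {"enabled": False, "pairs": []},
    "sasa": {"enabled": False, "sites": {}, "probe": 1.4, "n_sphere_points": 960, "stride": 1},
    "gbsa": {
        "enabled": False,
        "part_a": "",
        "part_b": "",
        "n_energy_snapshots": 2500,
        "n_entropy_snapshots": 50,
        "entropy": False,
        "decompose": False,
        "threshold": -1.0,
        "eps_in": 1.0,
        "eps_out": 78.5,
        "gamma": 0.00542,
        "beta": 0.92,
        "temperature": 310.0,
    },
}


@dataclass
class SystemConfig:
    name: str
    topology: str
    replicas: list[str]
    parameters: str | None = None
    frame_policy: str = "last_half"


@dataclass
class StudyConfig:
    systems: dict[str, SystemConfig]
    selections: dict[str, str]
    stages: dict[str, dict]
    output_dir: str = "allodyn_out"
    seed: int = 0
    fit_selection: str = ""
    compare_reference: str | None = None


@dataclass
class ReplicaAggregate:
    """Per-replica scalar values with their mean and sample sd."""

    values: list[float]
    mean: float
    sd: float | None

    @classmethod
    def of(cls, values) -> "ReplicaAggregate":
        vals = [float(v) for v in values]
        if not vals:
            raise InputError("no replica values to aggregate")
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        return cls(vals, float(np.mean(vals)), sd)


def aggregate_replicas(values) -> ReplicaAggregate:
    """Arithmetic mean and sample sd of per-replica scalar values."""
    return ReplicaAggregate.of(values)


_TOP_KEYS = {"systems", "selections", "stages", "output_dir", "seed", "fit_selection", "compare"}
_SYSTEM_KEYS = {"topology", "parameters", "replicas", "frame_policy"}


def load_config(path) -> StudyConfig:
    """Parse and validate a study config; every violation is reported at once."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config not parseable: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    errors: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")
    systems: dict[str, SystemConfig] = {}
    for name, sc in (raw.get("systems") or {}).items():
        for key in sc:
            if key not in _SYSTEM_KEYS:
                errors.append(f"system {name}: unknown key {key!r}")
        top_path = sc.get("topology")
        if not top_path:
            errors.append(f"system {name}: missing topology path")
        elif not Path(top_path).exists():
            errors.append(f"system {name}: topology {top_path} does not exist")
        params = sc.get("parameters")
        if params and not Path(params).exists():
            errors.append(f"system {name}: parameter file {params} does not exist")
        replicas = sc.get("replicas") or []
        if not replicas:
            errors.append(f"system {name}: no replica trajectories")
        for r in replicas:
            if not Path(r).exists():
                errors.append(f"system {name}: replica {r} does not exist")
        policy = sc.get("frame_policy", "last_half")
        if policy not in ("last_half", "all"):
            errors.append(f"system {name}: unknown frame_policy {policy!r}")
        systems[name] = SystemConfig(name, str(top_path), [str(r) for r in replicas],
                                     str(params) if params else None, policy)
    if not systems:
        errors.append("no systems defined")
    stages: dict[str, dict] = {}
    for stage, defaults in _STAGE_DEFAULTS.items():
        given = (raw.get("stages") or {}).get(stage) or {}
        for key in given:
            if key not in defaults:
                errors.append(f"stage {stage}: unknown key {key!r}")
        merged = {**defaults, **{k: v for k, v in given.items() if k in defaults}}
        stages[stage] = merged
    for stage in (raw.get("stages") or {}):
        if stage not in _STAGE_DEFAULTS:
            errors.append(f"unknown stage {stage!r}")
    occ = stages["network"]["occupancy_threshold"]
    if not 0 < occ <= 1:
        errors.append(f"network.occupancy_threshold {occ} outside (0, 1]")
    if stages["network"]["contact_cutoff"] <= 0:
        errors.append("network.contact_cutoff must be positive")
    if not 0 <= stages["saltbridges"]["min_population"] <= 1:
        errors.append("saltbridges.min_population outside [0, 1]")
    if stages["saltbridges"]["cutoff"] <= 0:
        errors.append("saltbridges.cutoff must be positive")
    if stages["sasa"]["probe"] < 0:
        errors.append("sasa.probe must be non-negative")
    compare_ref = (raw.get("compare") or {}).get("reference")
    if compare_ref is not None and compare_ref not in systems:
        errors.append(f"compare.reference {compare_ref!r} is not a defined system")
    if errors:
        raise ConfigError("invalid study config:\n  - " + "\n  - ".join(errors))
    return StudyConfig(
        systems=systems,
        selections={str(k): str(v) for k, v in (raw.get("selections") or {}).items()},
        stages=stages,
        output_dir=str(raw.get("output_dir", "allodyn_out")),
        seed=int(raw.get("seed", 0)),
        fit_selection=str(raw.get("fit_selection", "")),
        compare_reference=compare_ref,
    )


def _load_system(sys_cfg: SystemConfig, selections: dict[str, str]):
    top, ref_traj = read_structure(sys_cfg.topology)
    if sys_cfg.parameters:
        top = read_parameters(sys_cfg.parameters, top)
    top.named_selections.update(selections)
    replicas = []
    for path in sys_cfg.replicas:
        traj = read_trajectory(path, top)
        if sys_cfg.frame_policy == "last_half":
            traj = traj.last_half()
        replicas.append(traj)
    return top, ref_traj.coords[0], replicas


def _run_system(cfg: StudyConfig, sys_cfg: SystemConfig, outdir: Path) -> dict:
    stages = cfg.stages
    top, reference, replicas = _load_system(sys_cfg, cfg.selections)
    if cfg.fit_selection:
        fit = select(top, cfg.fit_selection)
        replicas = [superpose(t, reference, fit) for t in replicas]
    pooled = concatenate(replicas)
    report: dict = {"name": sys_cfg.name, "n_replicas": len(replicas)}

    if stages["pca"]["enabled"]:
        t0 = time.perf_counter()
        sel = select(top, stages["pca"]["selection"])
        pca = compute_pca(pooled, sel)
        ncomp = int(stages["pca"]["components"])
        scatter = pd.DataFrame(
            {"frame": np.arange(pooled.n_frames),
             **{f"PC{k + 1}": pca.projections[:, k] for k in range(ncomp)}}
        )
        scatter.to_csv(outdir / f"{sys_cfg.name}_pca_projections.csv", index=False)
        loadings = pd.DataFrame(
            {"residue": top.residue_resids[sel.residue_indices],
             "loading": pc_loadings(pca, 1)}
        )
        loadings.to_csv(outdir / f"{sys_cfg.name}_pc1_loadings.csv", index=False)
        report["pca"] = {
            "variance_fractions": pca.variance_fractions[:ncomp].tolist(),
            "eigenvalues": pca.eigenvalues[:ncomp].tolist(),
        }
        logger.info("[%s] pca: %d frames in %.2fs", sys_cfg.name, pooled.n_frames,
                    time.perf_counter() - t0)

    dccm = None
    if stages["dccm"]["enabled"] or stages["network"]["enabled"]:
        t0 = time.perf_counter()
        sel = select(top, stages["dccm"]["selection"])
        per_rep = [compute_dccm(t, sel) for t in replicas]
        dccm = average_dccm(per_rep)
        pd.DataFrame(dccm.matrix, index=dccm.residue_resids, columns=dccm.residue_resids).to_csv(
            outdir / f"{sys_cfg.name}_dccm.csv"
        )
        report["dccm"] = {"n_residues": dccm.n_residues}
        logger.info("[%s] dccm: %.2fs", sys_cfg.name, time.perf_counter() - t0)

    if stages["network"]["enabled"]:
        t0 = time.perf_counter()
        net = build_network(
            pooled,
            dccm,
            contact_cutoff=stages["network"]["contact_cutoff"],
            occupancy_threshold=stages["network"]["occupancy_threshold"],
            neighbor_exclusion=stages["network"]["neighbor_exclusion"],
        )
        export_edges(net).to_csv(outdir / f"{sys_cfg.name}_network_edges.csv", index=False)
        paths = []
        path_rows = []
        for spec in stages["network"]["paths"]:
            p = optimal_path(net, int(spec["source"]), int(spec["sink"]))
            paths.append(p)
            path_rows.append(
                {"source": spec["source"], "sink": spec["sink"],
                 "found": p is not None,
                 "nodes": "-".join(map(str, p.nodes)) if p else "",
                 "total_weight": p.total_weight if p else np.nan}
            )
        path_report(paths, top).to_csv(outdir / f"{sys_cfg.name}_paths_edges.csv", index=False)
        pd.DataFrame(path_rows, columns=["source", "sink", "found", "nodes", "total_weight"]).to_csv(
            outdir / f"{sys_cfg.name}_paths.csv", index=False
        )
        report["network"] = {
            "n_edges": net.n_edges,
            "paths": path_rows,
        }
        logger.info("[%s] network: %d edges in %.2fs", sys_cfg.name, net.n_edges,
                    time.perf_counter() - t0)

    if stages["saltbridges"]["enabled"]:
        sel_a = select(top, stages["saltbridges"]["selection_a"])
        sel_b = select(top, stages["saltbridges"]["selection_b"])
        records = scan_interface_salt_bridges(
            pooled, sel_a, sel_b,
            cutoff=stages["saltbridges"]["cutoff"],
            min_population=stages["saltbridges"]["min_population"],
            starting_frame=reference,
        )
        rows = []
        for rec in records:
            per_rep = [
                float(np.mean(distance_series(t, *_bridge_groups(t, rec)) <= stages["saltbridges"]["cutoff"]))
                for t in replicas
            ]
            rows.append(
                {"pair": rec.label, "basic": rec.basic_residue, "acidic": rec.acidic_residue,
                 "population": rec.population, "class": rec.bridge_class,
                 **{f"replica_{k}": v for k, v in enumerate(per_rep)}}
            )
        pd.DataFrame(rows).to_csv(outdir / f"{sys_cfg.name}_saltbridges.csv", index=False)
        report["saltbridges"] = rows
        logger.info("[%s] saltbridges: %d records", sys_cfg.name, len(rows))

    if stages["distances"]["enabled"]:
        series = {}
        for pair in stages["distances"]["pairs"]:
            ga = select(top, pair["group_a"])
            gb = select(top, pair["group_b"])
            series[pair["name"]] = distance_series(
                pooled, ga, gb, pair.get("mode", "min")
            )
        df = pd.DataFrame({"frame": np.arange(pooled.n_frames), **series})
        df.to_csv(outdir / f"{sys_cfg.name}_distances.csv", index=False)
        report["distances"] = {k: float(v.mean()) for k, v in series.items()}

    if stages["sasa"]["enabled"]:
        t0 = time.perf_counter()
        rows = []
        site_means = {}
        for site_name, residues in stages["sasa"]["sites"].items():
            per_rep = [
                site_sasa(t, top, list(residues), stages["sasa"]["probe"],
                          stages["sasa"]["n_sphere_points"], stages["sasa"]["stride"],
                          site_name).mean
                for t in replicas
            ]
            agg = aggregate_replicas(per_rep)
            site_means[site_name] = agg.mean
            rows.append({"site": site_name, "mean": agg.mean,
                         "sd": agg.sd if agg.sd is not None else np.nan,
                         **{f"replica_{k}": v for k, v in enumerate(agg.values)}})
        pd.DataFrame(rows).to_csv(outdir / f"{sys_cfg.name}_sasa.csv", index=False)
        report["sasa"] = site_means
        logger.info("[%s] sasa: %.2fs", sys_cfg.name, time.perf_counter() - t0)

    if stages["gbsa"]["enabled"]:
        t0 = time.perf_counter()
        g = stages["gbsa"]
        opts = EnergyOptions(
            eps_in=g["eps_in"], eps_out=g["eps_out"], gamma=g["gamma"], beta=g["beta"],
            temperature=g["temperature"], n_energy_snapshots=g["n_energy_snapshots"],
            n_entropy_snapshots=g["n_entropy_snapshots"], entropy=g["entropy"],
        )
        part_a = select(top, g["part_a"])
        part_b = select(top, g["part_b"])
        per_rep = []
        rows = []
        for k, t in enumerate(replicas):
            dec = binding_free_energy(t, top, part_a, part_b, opts)
            per_rep.append(dec.delta_g)
            rows.append({"replica": k, "delta_g": dec.delta_g, **dec.term_means,
                         "minus_t_delta_s": dec.minus_t_delta_s})
        agg = aggregate_replicas(per_rep)
        pd.DataFrame(rows).to_csv(outdir / f"{sys_cfg.name}_gbsa_terms.csv", index=False)
        report["gbsa"] = {"delta_g": agg.mean,
                          "sd": agg.sd,
                          "replicas": agg.values}
        if g["decompose"]:
            dec = per_residue_decomposition(pooled, top, part_a, part_b, opts, g["threshold"])
            df = pd.DataFrame(
                sorted(dec.per_residue.items()), columns=["residue", "contribution"]
            )
            df["significant"] = df["residue"].isin(dec.significant)
            df.to_csv(outdir / f"{sys_cfg.name}_gbsa_residues.csv", index=False)
            report["gbsa"]["per_residue"] = dec.per_residue
            report["gbsa"]["significant"] = dec.significant
        logger.info("[%s] gbsa: %.2fs", sys_cfg.name, time.perf_counter() - t0)

    return report


def _bridge_groups(traj, rec):
    top = traj.topology
    from .interface import _charged_group, _residue_ordinal

    ka = _residue_ordinal(top, rec.basic_residue)
    kb = _residue_ordinal(top, rec.acidic_residue)
    return (_charged_group(top, ka, "basic", rec.basic_atoms),
            _charged_group(top, kb, "acidic", rec.acidic_atoms))


def run_study(config: StudyConfig) -> dict:
    """Run every enabled stage for every system; returns the report bundle.

    Stage failures are recorded per system and the run continues with the
    remaining independent stages; ``bundle["errors"]`` lists all failures.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"systems": {}, "errors": []}
    for name, sys_cfg in config.systems.items():
        try:
            bundle["systems"][name] = _run_system(config, sys_cfg, outdir)
        except Exception as exc:  # noqa: BLE001 - isolate per-system failures
            logger.error("system %s failed: %s", name, exc)
            bundle["errors"].append({"system": name, "error": str(exc)})
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "systems": {
            n: {"topology": s.topology, "parameters": s.parameters,
                "replicas": s.replicas, "frame_policy": s.frame_policy}
            for n, s in config.systems.items()
        },
        "selections": config.selections,
        "fit_selection": config.fit_selection,
        "stages": config.stages,
        "errors": bundle["errors"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    if config.compare_reference:
        comparison = compare_systems(
            bundle["systems"].get(config.compare_reference, {}),
            {n: r for n, r in bundle["systems"].items() if n != config.compare_reference},
        )
        bundle["comparison"] = comparison
        with open(outdir / "comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=1, sort_keys=True)
    return bundle


def percent_of_reference(values: dict, reference_key) -> dict:
    """Express each entry as a nearest-integer percentage of a reference entry.

    E.g. per-residue binding contributions {K14: −5.6, R23: −5.0} with K14 as
    reference give {K14: 100, R23: 89}.
    """
    if reference_key not in values:
        raise InputError(f"reference {reference_key!r} not among values")
    ref = float(values[reference_key])
    if ref == 0:
        raise InputError("reference value is zero")
    return {k: int(round(100.0 * float(v) / ref)) for k, v in values.items()}


def compare_systems(reference_report: dict, other_reports: dict[str, dict]) -> dict:
    """Differences, percent changes, and ratios of each system vs a reference.

    Stages missing from one side yield explicit gaps rather than errors.
    """
    out: dict = {}
    for name, rep in other_reports.items():
        entry: dict = {}
        ref_g = (reference_report.get("gbsa") or {}).get("delta_g")
        sys_g = (rep.get("gbsa") or {}).get("delta_g")
        if ref_g is not None and sys_g is not None:
            entry["delta_g"] = {
                "reference": ref_g,
                "system": sys_g,
                "difference": sys_g - ref_g,
                "affinity_ratio": sys_g / ref_g if ref_g else None,
            }
        else:
            entry["delta_g"] = None
        sasa_ref = reference_report.get("sasa") or {}
        sasa_sys = rep.get("sasa") or {}
        sites = {}
        for site in sorted(set(sasa_ref) | set(sasa_sys)):
            if site in sasa_ref and site in sasa_sys and sasa_ref[site]:
                sites[site] = {
                    "reference": sasa_ref[site],
                    "system": sasa_sys[site],
                    "percent_change": 100.0 * (sasa_sys[site] - sasa_ref[site]) / sasa_ref[site],
                }
            else:
                sites[site] = None
        entry["sasa"] = sites
        pr_ref = (reference_report.get("gbsa") or {}).get("per_residue") or {}
        pr_sys = (rep.get("gbsa") or {}).get("per_residue") or {}
        if pr_ref and pr_sys:
            entry["per_residue_delta"] = {
                str(r): pr_sys.get(r, 0.0) - pr_ref.get(r, 0.0)
                for r in sorted(set(pr_ref) | set(pr_sys))
            }
        out[name] = entry
    return out
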