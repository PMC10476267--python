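"""End-to-end orchestration: simulate or ingest, normalize, analyze, report.

``run_all`` drives every stage from a single :class:`RunConfig` (loadable
from YAML), writes all result tables as TSV plus a JSON manifest, and is
byte-identical across reruns at a fixed seed. Stage failures abort with the
stage name; protein counts in and out of every stage are recorded so the
bookkeeping (e.g. how many proteins the vehicle-only exclusion removed) is
auditable from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from importlib.metadata import version as pkg_version
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import clustering, io, sets, stagewise
from . import longitudinal
from .errors import PipelineError, TmtBridgeError
from .normalize import bridge_spread, normalize as _normalize
from .simulate import (
    SimulationConfig,
    generate_ground_truth,
    simulate_multiplexes,
    write_simulation,
)

CONDITIONS = io.CONDITIONS
STAGES = stagewise.STAGES


@dataclass
class RunConfig:
    """Everything one run needs; simulation block and input paths are exclusive."""

    outdir: str = "results"
    #: Simulation settings (dict of SimulationConfig fields) or None to ingest.
    simulation: dict[str, Any] | None = None
    #: Input paths when not simulating: {"matrices": {mux: path}, "design": path}.
    inputs: dict[str, Any] | None = None
    alpha_mr: float = 0.05
    alpha_de: float = 0.05
    fc_log2: float = 1.0
    k: int = 5
    cluster_seed: int = 17
    n_restarts: int = 50
    reference: str = "M"
    channel_normalization: bool = True
    min_stages_highly_regulated: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_mr", "alpha_de", "fc_log2"):
            if getattr(self, name) <= 0:
                raise PipelineError("config", f"{name} must be positive")
        if (self.simulation is None) == (self.inputs is None):
            raise PipelineError(
                "config", "exactly one of 'simulation' and 'inputs' must be given"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _simulation_config(cfg: RunConfig) -> SimulationConfig:
    block = dict(cfg.simulation or {})
    block.setdefault("seed", cfg.seed)
    if "effect_grid" in block:
        block["effect_grid"] = [tuple(e) for e in block["effect_grid"]]
    if "archetype_offsets" in block:
        block["archetype_offsets"] = {
            k: tuple(v) for k, v in block["archetype_offsets"].items()
        }
    return SimulationConfig(**block)


def _load_inputs(cfg: RunConfig) -> tuple[list[io.ReporterMatrix], io.MultiplexDesign]:
    paths = cfg.inputs or {}
    design_path = paths.get("design")
    if not design_path or not Path(design_path).exists():
        raise PipelineError("ingest", f"design file missing: {design_path}")
    design = io.read_design(design_path)
    matrices = []
    for mux in design.multiplexes:
        mpath = (paths.get("matrices") or {}).get(mux)
        if not mpath or not Path(mpath).exists():
            raise PipelineError("ingest", f"matrix path missing for multiplex {mux!r}: {mpath}")
        matrices.append(io.read_reporter_matrix(mpath, design, mux))
    return matrices, design


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full pipeline; return the manifest (also written as JSON)."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "tmtbridge",
        "version": pkg_version("tmtbridge"),
        "config": {k: v for k, v in asdict(config).items() if k != "outdir"},
        "stages": {},
        "notes": [
            "t tests compare replicate log2 bridged intensities across multiplexes",
            "trajectory = (std log2 mean M, std log2FC EM_vs_M, std log2FC LM_vs_M)",
            "vehicle correction = subtraction of per-protein within-multiplex untreated mean",
        ],
    }

    try:
        # --- inputs ---------------------------------------------------------
        if config.simulation is not None:
            sim_cfg = _simulation_config(config)
            truth = generate_ground_truth(sim_cfg)
            matrices, design = simulate_multiplexes(truth, sim_cfg)
            write_simulation(truth, matrices, design, out / "simulated")
            manifest["stages"]["simulate"] = {
                "n_proteins": len(truth),
                "archetype_counts": truth["archetype"].value_counts().sort_index().to_dict(),
            }
        else:
            truth = None
            matrices, design = _load_inputs(config)
            manifest["stages"]["ingest"] = {
                "n_proteins": [len(m.protein_ids) for m in matrices]
            }

        # --- normalization --------------------------------------------------
        try:
            bridged = _normalize(
                matrices, design,
                reference=config.reference,
                channel_normalization=config.channel_normalization,
            )
        except TmtBridgeError as exc:
            raise PipelineError("normalize", str(exc)) from exc
        if bridged.channel_factors is not None:
            io.write_table(
                bridged.channel_factors.rename_axis("channel").reset_index(),
                out / "channel_factors.tsv",
            )
        bridged_out = pd.concat(
            [bridged.log2, bridged.bridge_log2.add_prefix("bridge:")], axis=1
        )
        io.write_table(bridged_out, out / "bridged.tsv", index_label="protein_id")
        manifest["stages"]["normalize"] = {
            "reference": bridged.reference,
            "n_retained": len(bridged.protein_ids),
            "n_dropped_missing_bridge": len(bridged.dropped),
            "bridge_log2_spread_max": bridge_spread(bridged),
        }

        # --- longitudinal MR per condition ----------------------------------
        mr_sets: dict[str, set[str]] = {}
        for condition in CONDITIONS:
            try:
                calls = longitudinal.mr_analysis(
                    bridged, condition, config.alpha_mr, config.fc_log2
                )
            except TmtBridgeError as exc:
                raise PipelineError(f"longitudinal:{condition}", str(exc)) from exc
            io.write_table(calls, out / f"mr_{condition}.tsv", index_label="protein_id")
            mr_sets[condition] = longitudinal.mr_set(calls)
            manifest["stages"][f"mr_{condition}"] = {
                "n_tested": len(calls),
                "n_mr": len(mr_sets[condition]),
            }

        # --- Venn + vehicle-only exclusion ----------------------------------
        partitions = sets.mr_venn(
            mr_sets["untreated"], mr_sets["vehicle"], mr_sets["tmx"]
        )
        tmx_cluster_input = sets.exclude_vehicle_only(partitions)
        venn_df = pd.DataFrame(
            {
                "region": list(sets.VENN_REGIONS),
                "size": [len(partitions[r]) for r in sets.VENN_REGIONS],
                "members": [";".join(sorted(partitions[r])) for r in sets.VENN_REGIONS],
            }
        )
        io.write_table(venn_df, out / "mr_venn.tsv")
        manifest["stages"]["venn"] = {
            "sizes": {r: len(partitions[r]) for r in sets.VENN_REGIONS},
            "tmx_mr_total": len(mr_sets["tmx"]),
            "tmx_cluster_input": len(tmx_cluster_input),
            "n_vehicle_only_excluded": len(mr_sets["tmx"]) - len(tmx_cluster_input),
        }

        # --- trajectory clustering + cross-condition match ------------------
        cluster_models: dict[str, clustering.ClusterModel] = {}
        for condition, protein_set in (
            ("untreated", mr_sets["untreated"]),
            ("tmx", tmx_cluster_input),
        ):
            try:
                traj = clustering.build_trajectories(bridged, protein_set, condition)
                model = clustering.kmeans_cluster(
                    traj, k=config.k, seed=config.cluster_seed, n_restarts=config.n_restarts
                )
            except TmtBridgeError as exc:
                raise PipelineError(f"cluster:{condition}", str(exc)) from exc
            cluster_models[condition] = model
            io.write_table(
                pd.concat([traj, model.assignments], axis=1),
                out / f"clusters_{condition}.tsv",
                index_label="protein_id",
            )
            manifest["stages"][f"cluster_{condition}"] = {
                "k": model.k,
                "inertia": model.inertia,
                "sizes": model.sizes.to_dict(),
            }
        match = clustering.match_clusters(cluster_models["untreated"], cluster_models["tmx"])
        io.write_table(match.overlap, out / "cluster_overlap.tsv")
        manifest["stages"]["cluster_match"] = {
            "mapping": {str(a): b for a, b in match.mapping.items()},
            "total_centroid_distance": match.total_distance,
        }

        # --- stagewise DE ----------------------------------------------------
        de_calls = {}
        for stage in STAGES:
            try:
                calls = stagewise.stage_de(bridged, stage, config.alpha_de, config.fc_log2)
            except TmtBridgeError as exc:
                raise PipelineError(f"de:{stage}", str(exc)) from exc
            de_calls[stage] = calls
            io.write_table(calls, out / f"de_{stage}.tsv", index_label="protein_id")
        de_total = stagewise.de_union(de_calls)
        manifest["stages"]["de"] = {
            "per_stage": {s: int(de_calls[s]["is_de"].sum()) for s in STAGES},
            "union": len(de_total),
        }

        # --- DE x MR set report ----------------------------------------------
        inter = sets.de_mr_intersections(de_total, mr_sets["untreated"], mr_sets["tmx"])
        inter_df = pd.DataFrame(
            {
                "subset": list(inter),
                "size": [len(v) for v in inter.values()],
                "members": [";".join(sorted(v)) for v in inter.values()],
            }
        )
        io.write_table(inter_df, out / "de_mr.tsv")
        hr = sets.highly_regulated(de_calls, config.min_stages_highly_regulated)
        io.write_table(hr, out / "highly_regulated.tsv", index_label="protein_id")
        manifest["stages"]["sets"] = {
            "de_and_mr_untreated": len(inter["de_and_mr_untreated"]),
            "added_to_program": len(inter["added_to_program"]),
            "outside_program": len(inter["outside_program"]),
            "highly_regulated": len(hr),
            "highly_regulated_all_stages": int((hr["n_stages"] == len(STAGES)).sum())
            if len(hr) else 0,
        }
    except PipelineError:
        (out / "manifest.json").write_text(
            json.dumps({**manifest, "status": "failed"}, indent=2, sort_keys=True)
        )
        raise

    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
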