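"""End-to-end orchestration: simulate → metrics → states/dimers → summaries.

A single structured YAML config drives every stage; each output directory
carries exactly one run manifest (config snapshot, input digests, package
version, seed, timestamp) so that a rerun with identical inputs reproduces
the deterministic outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dimers import DimerConfig, dimer_statistics, events_from_pair_metrics
from .geometry import NanoparticleModel, pair_metrics, trajectory_metrics
from .states import (
    ClassifierConfig,
    adsorbed_percentage,
    segments_from_metrics,
)
from .synthetic import (
    DimerInterval,
    NPSpec,
    Script,
    SimConfig,
    StateInterval,
    TrimerScript,
    simulate_trajectory,
)
from .trajio import (
    Trajectory,
    read_topology,
    read_trajectory,
    write_table,
    write_topology,
    write_trajectory,
)

__all__ = ["PipelineError", "load_config", "run_pipeline", "write_manifest"]


class PipelineError(ValueError):
    """Configuration or stage failure with a named cause."""


_TOP_KEYS = {"seed", "simulate", "inputs", "classifier", "dimer", "np_radius_A",
             "save_trajectory"}
_SIM_KEYS = {
    "mode", "n_dye", "dye_site_count", "core_site_count", "nps", "d_t", "d_r",
    "timestep", "duration", "attraction_kt", "adsorption_gate_deg",
    "stacking_depth", "stacking_gate_deg", "debye_length", "noise_sd",
    "confinement_radius", "script",
}
_NP_KEYS = {"center", "radius", "well_depth", "n_sites", "total_charge"}
_SCRIPT_KEYS = {"states", "dimers", "trimers"}


def _check_keys(mapping: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise PipelineError(
            f"unknown config key(s) {sorted(unknown)} in {where}"
        )


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and schema-validate a pipeline config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise PipelineError("config must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    if "simulate" in cfg and "inputs" in cfg:
        raise PipelineError("config must use either 'simulate' or 'inputs'")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise PipelineError("config needs a 'simulate' or 'inputs' section")
    if "simulate" in cfg:
        _check_keys(cfg["simulate"], _SIM_KEYS, "simulate")
        for np_block in cfg["simulate"].get("nps", []):
            _check_keys(np_block, _NP_KEYS, "simulate.nps")
        if cfg["simulate"].get("script"):
            _check_keys(cfg["simulate"]["script"], _SCRIPT_KEYS, "simulate.script")
    return dict(cfg)


def sim_config_from_mapping(sim: Mapping[str, Any], seed: int) -> SimConfig:
    """Build a :class:`SimConfig` from the validated config block."""
    sim = dict(sim)
    sim.pop("mode", None)
    nps = [NPSpec(**{**n, "center": tuple(n.get("center", (0, 0, 0)))})
           for n in sim.pop("nps", [{}])]
    script_block = sim.pop("script", None)
    script = None
    if script_block:
        states = {
            int(d): [StateInterval(**iv) for iv in ivs]
            for d, ivs in (script_block.get("states") or {}).items()
        }
        dimers = [DimerInterval(**e) for e in script_block.get("dimers") or []]
        trimers = [TrimerScript(**t) for t in script_block.get("trimers") or []]
        script = Script(states=states, dimers=dimers, trimers=trimers)
    return SimConfig(nps=nps, seed=seed, script=script, **sim)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: Path, config: Mapping[str, Any], seed: int, inputs: Mapping[str, Path]
) -> None:
    manifest = {
        "tool": "dyesorb",
        "version": __version__,
        "seed": seed,
        "config": json.loads(json.dumps(config, default=str)),
        "input_digests": {k: _digest(Path(p)) for k, p in inputs.items()},
        "created": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config_path: str | Path, outdir: str | Path) -> Path:
    """Run the full analysis described by a config file.

    Writes per-frame metrics, state segments, dimer events, an
    adsorbed-percentage summary, dimer statistics and one manifest into
    *outdir*.  Partial outputs are removed on failure.
    """
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        cfg = load_config(config_path)
        seed = int(cfg.get("seed", 0))
        inputs: dict[str, Path] = {"config": config_path}

        if "simulate" in cfg:
            sim_cfg = sim_config_from_mapping(cfg["simulate"], seed)
            traj, top, gt = simulate_trajectory(sim_cfg)
            radius_map = {f"SNP{k + 1}": s.radius for k, s in enumerate(sim_cfg.nps)}
            np_models = [
                NanoparticleModel(
                    label=g,
                    centers=np.asarray(sim_cfg.nps[k].center, dtype=float),
                    radius=sim_cfg.nps[k].radius,
                )
                for k, g in enumerate(radius_map)
            ]
            if cfg.get("save_trajectory", False):
                write_topology(top, outdir / "topology.pdb")
                write_trajectory(traj, outdir / "trajectory.tsv")
                created += [outdir / "topology.pdb", outdir / "trajectory.tsv"]
            gt_rows = [
                {"dye": f"R6G_{d + 1}", "label": iv.label, "start": iv.start,
                 "end": iv.end, "np_index": iv.np_index}
                for d, ivs in sorted(gt.states.items()) for iv in ivs
            ]
            pd.DataFrame(
                gt_rows, columns=["dye", "label", "start", "end", "np_index"]
            ).to_csv(outdir / "ground_truth_states.tsv", sep="\t", index=False)
            created.append(outdir / "ground_truth_states.tsv")
        else:
            inp = cfg["inputs"]
            top = read_topology(inp["topology"], inp.get("sidecar"))
            traj = read_trajectory(inp["trajectory"], top)
            np_models = None
            inputs["topology"] = Path(inp["topology"])
            inputs["trajectory"] = Path(inp["trajectory"])

        cls_cfg = ClassifierConfig(**(cfg.get("classifier") or {}))
        dim_cfg = DimerConfig(**(cfg.get("dimer") or {}))

        metrics = trajectory_metrics(
            traj, np_models=np_models, np_diameter=cfg.get("np_radius_A", 20.0) * 2
            if np_models is None else None,
        )
        metrics.to_csv(
            outdir / "metrics.tsv", sep="\t", index=False, float_format="%.4f"
        )
        created.append(outdir / "metrics.tsv")

        segments = segments_from_metrics(metrics, cls_cfg)
        write_table(segments, outdir / "segments.tsv", kind="state_segments")
        created.append(outdir / "segments.tsv")

        pm = pair_metrics(
            traj, np_models=np_models, np_diameter=cfg.get("np_radius_A", 20.0) * 2
            if np_models is None else None,
        )
        events, trimers = events_from_pair_metrics(pm, dim_cfg, segments)
        write_table(
            [
                {"pair": e.pair_label, "start": e.start, "end": e.end,
                 "location": e.location, "end_reason": e.end_reason}
                for e in events
            ],
            outdir / "dimer_events.tsv",
            kind="dimer_events",
        )
        created.append(outdir / "dimer_events.tsv")

        length = traj.length_ns
        pct = adsorbed_percentage(segments, length)
        stats = dimer_statistics({"run": events})
        summary = pd.DataFrame(
            [
                {
                    "trajectory_length_ns": length,
                    "adsorbed_percent": pct,
                    "n_segments_A": sum(s.label == "A" for s in segments),
                    "n_segments_RA": sum(s.label == "RA" for s in segments),
                    "n_segments_T": sum(s.label == "T" for s in segments),
                    "n_dimer_events": len(events),
                    "n_trimer_intervals": len(trimers),
                    "dimer_total_time_ns": stats.total_time,
                    "dimer_mean_lifetime_ns": stats.mean_lifetime,
                }
            ]
        )
        summary.to_csv(
            outdir / "summary.tsv", sep="\t", index=False, float_format="%.4f"
        )
        created.append(outdir / "summary.tsv")

        write_manifest(outdir, cfg, seed, inputs)
        return outdir
    except Exception:
        for p in created:
            if p.exists():
                p.unlink()
        raise
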