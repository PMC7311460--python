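"""Reproducible stage chaining: simulate -> test -> evaluate -> ruv -> becorrect.

A :class:`RunConfig` (typically loaded from YAML) names the stages to run
and their parameters.  Every stochastic stage derives its seed
deterministically from the global seed and the stage name, so adding a
stage never perturbs earlier stages' randomness, and a manifest (inputs,
seeds, versions, output checksums) is written so any summary row can be
regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .becorrect import correct_track, parse_bedgraph, read_peak_table, write_bedgraph
from .da import MethodSpec, run_method
from .evaluate import aggregate_sweep, benchmark_sweep
from .ruv import ruvr_correct
from .simulate import SimulationDesign, simulate_counts
from .tables import (
    FLOAT_FORMAT,
    read_matrix_files,
    write_count_table,
    write_matrix_files,
    write_result_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "derive_seed", "run_pipeline"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Structured description of one pipeline run."""

    stages: list[dict]
    outdir: str
    seed: int = 0
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = {"stages", "outdir", "seed", "log_level"}
        extras = {k: v for k, v in doc.items() if k not in known}
        return cls(
            stages=doc["stages"],
            outdir=doc["outdir"],
            seed=int(doc.get("seed", 0)),
            log_level=doc.get("log_level", "INFO"),
            extras=extras,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(params: dict, outdir: Path, seed: int) -> dict:
    design = SimulationDesign(
        depth=float(params.get("depth", 30e6)),
        sd_fraction=float(params.get("sd", 0.10)),
        replicates_per_condition=int(params.get("replicates", 3)),
        n_repeats=int(params.get("repeats", 1)),
        seed=seed,
        n_peaks=params.get("n_peaks"),
    )
    outputs = {}
    for i in range(design.n_repeats):
        matrix = simulate_counts(design, repeat=i)
        outputs[f"repeat_{i}"] = write_matrix_files(matrix, outdir, prefix=f"sim{i:02d}")
    return outputs


def _stage_test(params: dict, outdir: Path) -> dict:
    matrix = read_matrix_files(
        params["counts"], params["design"], params.get("truth")
    )
    spec = MethodSpec(
        name=params["method"],
        prior_count=float(params.get("prior_count", 2.0)),
        batch_covariate=bool(params.get("batch_covariate", False)),
        voom_weights=bool(params.get("voom_weights", False)),
        dispersion_mode=params.get("dispersion_mode", "common"),
        external_cmd=params.get("external_cmd"),
    )
    result = run_method(spec, matrix)
    out = outdir / params.get("out", f"result_{spec.name}.tsv")
    write_result_table(out, result)
    return {"result": str(out)}


def _stage_sweep(params: dict, outdir: Path, seed: int) -> dict:
    design = SimulationDesign(
        depth=float(params.get("depth", 30e6)),
        sd_fraction=float(params.get("sd", 0.10)),
        replicates_per_condition=int(params.get("replicates", 3)),
        n_repeats=int(params.get("repeats", 1)),
        seed=seed,
        n_peaks=params.get("n_peaks"),
    )
    methods = [MethodSpec(name=m) for m in params.get("methods", ["ttest"])]
    reps = params.get("replicate_counts") or [design.replicates_per_condition]
    sweep = benchmark_sweep(
        design, methods, replicate_counts=[int(k) for k in reps],
        cutoff=float(params.get("cutoff", 0.05)),
    )
    agg = aggregate_sweep(sweep)
    raw_path = outdir / "sweep_repeats.tsv"
    agg_path = outdir / "sweep_summary.tsv"
    sweep.to_csv(raw_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    agg.to_csv(agg_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return {"repeats": str(raw_path), "summary": str(agg_path)}


def _stage_ruv(params: dict, outdir: Path) -> dict:
    matrix = read_matrix_files(params["counts"], params["design"], params.get("truth"))
    corrected, model = ruvr_correct(
        matrix.counts,
        matrix.condition,
        k=int(params.get("k", 3)),
        norm=params.get("norm", "colsum"),
    )
    out = outdir / params.get("out", "corrected_counts.tsv")
    write_count_table(out, corrected, matrix.peak_ids, matrix.samples)
    w_path = outdir / params.get("factors_out", "unwanted_factors.tsv")
    np.savetxt(w_path, model.W, delimiter="\t", fmt=FLOAT_FORMAT,
               header="\t".join(f"W{j + 1}" for j in range(model.k)), comments="")
    return {"corrected": str(out), "factors": str(w_path)}


def _stage_becorrect(params: dict, outdir: Path) -> dict:
    track = parse_bedgraph(params["bedgraph"])
    raw = read_peak_table(params["raw_counts"])
    adjusted = read_peak_table(params["adjusted_counts"])
    corrected = correct_track(
        track, raw, adjusted, params["sample"], per_base=bool(params.get("per_base", False))
    )
    out = outdir / params.get("out", "corrected.bedgraph")
    write_bedgraph(corrected, out)
    return {"bedgraph": str(out)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stage chain; returns the artifact directory.

    Writes ``manifest.json`` recording the package version, global seed,
    per-stage derived seeds and parameters, and a sha256 checksum for every
    output file, so each artifact is re-derivable from the manifest alone.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    for stage in config.stages:
        name = stage["stage"]
        params = {k: v for k, v in stage.items() if k != "stage"}
        seed = derive_seed(config.seed, name)
        logger.info("running stage %s (derived seed %d)", name, seed)
        try:
            if name == "simulate":
                outputs = _stage_simulate(params, outdir, seed)
            elif name == "test":
                outputs = _stage_test(params, outdir)
            elif name == "sweep":
                outputs = _stage_sweep(params, outdir, seed)
            elif name == "ruv":
                outputs = _stage_ruv(params, outdir)
            elif name == "becorrect":
                outputs = _stage_becorrect(params, outdir)
            else:
                raise ValueError(f"unknown stage {name!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"stage": name, "seed": seed, "params": params, "outputs": outputs}
        )
    checksums = {}
    for stage_entry in manifest["stages"]:
        for out in stage_entry["outputs"].values():
            if isinstance(out, dict):
                for p in out.values():
                    checksums[p] = _sha256(Path(p))
            else:
                checksums[out] = _sha256(Path(out))
    manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
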