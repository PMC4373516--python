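"""End-to-end orchestration: configuration, stage logging, report assembly.

Two modes, chosen by the config:

* ``simulate`` — generate an experiment from simulation parameters, then
  analyze it (filter -> coverage -> errors -> detection -> qc);
* ``analyze`` — read a multi-sample VCF (plus optional BED, bedGraphs and
  QC TSV) and run the same analysis stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__ as _version
from .config import SimulationConfig
from .filtering import FilterConfig
from .io import read_bed, read_bedgraph, read_qc_tsv, write_bedgraph, write_bed, \
    write_qc_tsv, write_truth_tsv, write_vcf
from .model import SingleCellErrorModel

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class MetricsReport:
    """All computed metrics plus a provenance block; JSON round-trippable."""

    report: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"report": self.report, "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        return cls(report=d["report"], provenance=d["provenance"])


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, out_dir=None, seed: int | None = None) -> MetricsReport:
    """Execute the full pipeline described by a YAML config (path or dict)."""
    cfg = load_config(config)
    mode = cfg.get("mode", "simulate")
    filt = FilterConfig(**cfg.get("filters", {}))
    qc_min = int(cfg.get("qc", {}).get("min_amplicons", 22))
    min_depth = filt.min_depth

    if mode == "simulate":
        sim_params = dict(cfg.get("simulation", {}))
        if seed is not None:
            sim_params["seed"] = int(seed)
        sim_config = SimulationConfig(**sim_params)
        qc_probs = cfg.get("qc", {}).get("pass_probabilities")
        log.info("stage simulate: target %d bp, %d cells, %d variant sites",
                 sim_config.target_size_bp, sim_config.n_cells,
                 sim_config.n_variants)
        model = SingleCellErrorModel.from_simulation(sim_config, qc_probs)
        model.filter_config = filt
        sim_dump = sim_config.to_dict()
    elif mode == "analyze":
        inputs = cfg.get("inputs", {})
        if "vcf" not in inputs:
            raise PipelineError("inputs", "analyze mode requires inputs.vcf")
        target = read_bed(inputs["bed"]) if inputs.get("bed") else None
        model = SingleCellErrorModel.from_vcf(
            inputs["vcf"], inputs.get("reference_sample", "population"),
            target=target, filter_config=filt)
        if inputs.get("bedgraphs"):
            if target is None:
                raise PipelineError("inputs", "bedgraphs require inputs.bed")
            model.depth_profiles = [read_bedgraph(p, target)
                                    for p in inputs["bedgraphs"]]
        if inputs.get("qc_tsv"):
            model.qc = read_qc_tsv(inputs["qc_tsv"])
        sim_dump = None
        log.info("stage load: %d reference records, %d cells",
                 len(model.reference), len(model.cells))
    else:
        raise PipelineError("config", f"unknown mode {mode!r}")

    log.info("stage filter: thresholds %s", vars(filt))
    results = model.fit(min_depth=min_depth, qc_min_amplicons=qc_min)
    for cell, filtered in zip(model.cells, results.filtered):
        log.info("stage filter: %s %d -> %d records",
                 filtered.cell_id, len(cell), len(filtered))
    log.info("stage errors: mean restricted ADR %.4f, mean FPR %.3g",
             results.errors.adr_restricted.mean, results.errors.fpr.mean)

    provenance = {
        "tool": "scwga",
        "version": _version,
        "mode": mode,
        "config_hash": _config_hash(cfg),
        "seed": sim_dump["seed"] if sim_dump else None,
    }
    report = MetricsReport(report=results.to_dict(), provenance=provenance)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "summary.txt").write_text(results.summary() + "\n")
        if mode == "simulate":
            _write_simulated_inputs(model, out)
    return report


def _write_simulated_inputs(model: SingleCellErrorModel, out: Path) -> None:
    """Persist the simulated experiment in standard formats."""
    write_vcf(out / "calls.vcf", model.reference, model.cells)
    if model.target is not None:
        write_bed(model.target, out / "target.bed")
    if model.depth_profiles:
        for cell, profile in zip(model.cells, model.depth_profiles):
            write_bedgraph(profile, out / f"{cell.cell_id}.depth.bedgraph")
    if model.truth is not None:
        write_truth_tsv(model.truth, out / "truth.tsv")
    if model.qc is not None:
        write_qc_tsv(model.qc, out / "qc.tsv")
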