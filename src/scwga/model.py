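"""Model/Results facade over the metric suite.

``SingleCellErrorModel`` bundles a population reference, a set of single-
cell call sets and (optionally) depth profiles and a QC table; ``fit()``
applies the site filters and computes every error, detection and coverage
statistic, returning a ``SingleCellErrorResults`` object with the
estimates, their SEMs and a printable summary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .coverage import LorenzCurve, coverage_breadth, lorenz_curve, mean_depth
from .detection import DetectionReport, detection_efficiency
from .errors import ErrorReport, error_report
from .filtering import FilterConfig, apply_site_filters, filter_clustered_snvs
from .io import (INDEL, SNV, CellCallSet, DepthProfile, PopulationReference,
                 QCMatrix, TargetRegion, read_multisample_vcf)
from .qc import select_cells
from .simulate import SimulatedExperiment, simulate_experiment


class SingleCellErrorModel:
    """Technical-error model of a single-cell WGA sequencing experiment.

    Parameters
    ----------
    reference : PopulationReference
        Bulk truth set from the jointly called VCF.
    cells : list of CellCallSet
        One (unfiltered) call set per single cell.
    target : TargetRegion, optional
        Capture target; required for coverage metrics.
    depth_profiles : list of DepthProfile, optional
        Per-cell per-base depth (same order as ``cells``).
    qc : QCMatrix, optional
        qPCR amplification panel outcomes.
    filter_config : FilterConfig, optional
        Site-filter thresholds (defaults are the pipeline's standard:
        MQ >= 40, bq 20, depth >= 6, >= 2 alt reads, 10 bp cluster window).
    """

    def __init__(self, reference: PopulationReference, cells: list[CellCallSet],
                 *, target: TargetRegion | None = None,
                 depth_profiles: list[DepthProfile] | None = None,
                 qc: QCMatrix | None = None,
                 filter_config: FilterConfig | None = None,
                 truth=None):
        self.reference = reference
        self.cells = list(cells)
        self.target = target
        self.depth_profiles = depth_profiles
        self.qc = qc
        self.filter_config = filter_config or FilterConfig()
        self.truth = truth

    @classmethod
    def from_vcf(cls, path, reference_sample: str = "population", **kwargs
                 ) -> "SingleCellErrorModel":
        ref, cells = read_multisample_vcf(path, reference_sample)
        return cls(ref, cells, **kwargs)

    @classmethod
    def from_simulation(cls, config: SimulationConfig,
                        qc_pass_probabilities=None) -> "SingleCellErrorModel":
        exp: SimulatedExperiment = simulate_experiment(config, qc_pass_probabilities)
        return cls(exp.reference, exp.cells, target=exp.target,
                   depth_profiles=exp.depth_profiles, qc=exp.qc, truth=exp.truth)

    def filtered_cells(self, apply_cluster_filter: bool = True) -> list[CellCallSet]:
        """Threshold-filter (and optionally cluster-filter) every cell."""
        out = []
        for cell in self.cells:
            filtered = apply_site_filters(cell, self.filter_config)
            if apply_cluster_filter:
                filtered = filter_clustered_snvs(
                    filtered, self.filter_config.cluster_window_bp)
            out.append(filtered)
        return out

    def fit(self, min_depth: int = 6, qc_min_amplicons: int = 22,
            apply_cluster_filter: bool = True) -> "SingleCellErrorResults":
        filtered = self.filtered_cells(apply_cluster_filter)
        # derive the FPR denominator from depth tracks where the call sets
        # (e.g. read from a VCF) do not carry it
        if self.depth_profiles:
            for cell, profile in zip(filtered, self.depth_profiles):
                if cell.hom_ref_callable_bp is None:
                    cell.hom_ref_callable_bp = _hom_ref_callable_bp(
                        profile, self.reference, min_depth)
        errors = error_report(filtered, self.reference, min_depth=min_depth)
        detection = {
            (vt, restricted): detection_efficiency(
                self.reference, filtered, variant_type=vt,
                min_depth=min_depth, restricted=restricted)
            for vt in (SNV, INDEL) for restricted in (True, False)
        }
        coverage = None
        if self.depth_profiles:
            breadth = [coverage_breadth(p, min_depth=1) for p in self.depth_profiles]
            callable_ = [coverage_breadth(p, min_depth=min_depth)
                         for p in self.depth_profiles]
            depths = [mean_depth(p) for p in self.depth_profiles]
            lorenz = [lorenz_curve(p) for p in self.depth_profiles]
            coverage = CoverageSection(
                breadth_1x=_mean_sem(breadth), callable_fraction=_mean_sem(callable_),
                mean_depth=_mean_sem(depths),
                lorenz_uniformity=_mean_sem([c.uniformity_index for c in lorenz]),
                lorenz_curves=lorenz)
        qc_section = None
        if self.qc is not None:
            passing, rate = select_cells(self.qc, qc_min_amplicons)
            qc_section = {"min_amplicons": qc_min_amplicons,
                          "passing_cells": passing, "pass_rate": rate}
        return SingleCellErrorResults(model=self, filtered=filtered,
                                      errors=errors, detection=detection,
                                      coverage=coverage, qc=qc_section,
                                      min_depth=min_depth)


def _hom_ref_callable_bp(profile: DepthProfile, reference: PopulationReference,
                         min_depth: int) -> int:
    """Bases with cell depth >= min_depth that are hom-ref in the reference."""
    total = int((profile.all_depths() >= min_depth).sum())
    for chrom, grp in reference.variant_sites().groupby("chrom"):
        depths = profile.depth_at(chrom, grp["pos"].to_numpy())
        total -= int((depths >= min_depth).sum())
    return total


def _mean_sem(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return {"per_cell": [float(v) for v in arr], "mean": float(arr.mean()), "sem": sem}


@dataclass
class CoverageSection:
    breadth_1x: dict
    callable_fraction: dict
    mean_depth: dict
    lorenz_uniformity: dict
    lorenz_curves: list[LorenzCurve] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {"breadth_1x": self.breadth_1x,
                "callable_fraction": self.callable_fraction,
                "mean_depth": self.mean_depth,
                "lorenz_uniformity": self.lorenz_uniformity}


@dataclass
class SingleCellErrorResults:
    """Fitted error metrics with uncertainties and a summary table."""

    model: SingleCellErrorModel
    filtered: list[CellCallSet]
    errors: ErrorReport
    detection: dict[tuple[str, bool], DetectionReport]
    coverage: CoverageSection | None
    qc: dict | None
    min_depth: int

    def to_dict(self) -> dict:
        return {
            "n_cells": len(self.model.cells),
            "min_depth": self.min_depth,
            "errors": self.errors.to_dict(),
            "detection": {f"{vt}_{'restricted' if r else 'unrestricted'}":
                          rep.to_dict() for (vt, r), rep in self.detection.items()},
            "coverage": self.coverage.to_dict() if self.coverage else None,
            "qc": self.qc,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        e = self.errors
        lines = [
            "Single-cell WGA technical-error summary",
            "=" * 55,
            f"cells: {len(self.model.cells)}   min depth: {self.min_depth}X",
            "",
            "Allelic dropout (ref het -> cell hom)",
            f"  restricted (>= {self.min_depth}X both): "
            f"{_pct(e.adr_restricted.mean)} (SEM {_pct(e.adr_restricted.sem)})",
            f"  unrestricted (all het sites):  {_pct(e.adr_unrestricted.mean)}",
            f"  AB->BB fraction of dropouts:   {_pct(e.ado_bias)}",
            f"  recurrent dropout sites:       {_pct(e.ado_recurrence.fraction_recurrent)}"
            f" (mean multiplicity {e.ado_recurrence.mean_cells_per_recurrent_site:.2f})",
            "",
            "False positives (cell het at ref hom-ref)",
            f"  FPR: {e.fpr.mean:.3g} per base"
            f"  ({errors_fmt(e.fpr.mean)} errors/Mb)",
            f"  consensus rate, 2 cells: {e.consensus_fp_two_cells:.3g}",
        ]
        if e.spectrum.transition_fraction is not None:
            lines.append(f"  C>T + G>A transition fraction: "
                         f"{_pct(e.spectrum.transition_fraction)} "
                         f"(n = {e.spectrum.total})")
        lines.append(f"  recurrent FP sites: {_pct(e.fp_recurrence.fraction_recurrent)}")
        lines.append("")
        lines.append("Detection efficiency (bulk variant seen in cell)")
        for (vt, restricted), rep in sorted(self.detection.items(),
                                            key=lambda kv: (kv[0][0], not kv[0][1])):
            label = f"{vt} {'restricted' if restricted else 'unrestricted'}"
            lines.append(f"  {label:<22} {_pct(rep.efficiency.mean)}"
                         f"  (pooled {rep.pooled_detected}/{rep.pooled_total})")
        if self.coverage:
            c = self.coverage
            lines += [
                "",
                "Coverage",
                f"  breadth (>=1X):      {_pct(c.breadth_1x['mean'])}",
                f"  callable (>= {self.min_depth}X):   {_pct(c.callable_fraction['mean'])}",
                f"  mean depth:          {c.mean_depth['mean']:.2f}X",
                f"  Lorenz uniformity:   {c.lorenz_uniformity['mean']:.3f} (0 = uniform)",
            ]
        if self.qc:
            lines += [
                "",
                f"QC panel ({self.qc['min_amplicons']}/22 rule): "
                f"pass rate {_pct(self.qc['pass_rate'])} "
                f"({len(self.qc['passing_cells'])} cells)",
            ]
        return "\n".join(lines)


def _pct(x: float) -> str:
    return "n/a" if x is None or not np.isfinite(x) else f"{100 * x:.2f}%"


def errors_fmt(p: float) -> str:
    return "n/a" if not np.isfinite(p) else f"{p * 1e6:.1f}"
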