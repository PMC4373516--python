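"""Technical-error statistics for WGA single-cell call sets.

Two error classes dominate MDA-amplified single-cell data:

* **Allelic dropout (ADR)** — loss of one allele at a heterozygous site, so
  a true AB genotype is called AA or BB. Per cell,
  ``ADR_i = Hom_s / Het_p``: the fraction of population-het sites at which
  the cell is called homozygous (either allele lost). The headline
  ("restricted") estimate requires >= 6X depth in both the reference and
  the cell, excluding low-coverage sites where missingness rather than
  dropout explains the genotype; the "unrestricted" variant uses every
  reference-het site and counts an uncalled cell site as a dropout.
* **False positives (FPR)** — spurious het calls from polymerase
  misincorporation. Per cell, ``FPR_i = Het_s / Hom_p``: het calls at
  population hom-ref sites over the callable hom-ref denominator.

Across-cell summaries are the mean of per-cell rates with
SEM = sd / sqrt(n_cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SUBSTITUTION_CLASSES, TRANSITION_CLASSES
from .io import HET, HOM_ALT, HOM_REF, SNV, CellCallSet, PopulationReference

log = logging.getLogger(__name__)


@dataclass
class RateEstimate:
    """Per-cell rates plus their across-cell mean and SEM."""

    per_cell: dict[str, float]
    mean: float
    sem: float

    @property
    def values(self) -> list[float]:
        return list(self.per_cell.values())


def _summarize(per_cell: dict[str, float]) -> RateEstimate:
    vals = np.array(list(per_cell.values()), dtype=float)
    if vals.size == 0:
        return RateEstimate(per_cell, float("nan"), float("nan"))
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    return RateEstimate(per_cell, mean, sem)


def _cell_at_ref_sites(ref_sites: pd.DataFrame, cell: CellCallSet) -> pd.DataFrame:
    """Left-join cell records onto reference sites by (chrom, pos);
    unmatched sites come back with NaN cell columns (no-call)."""
    cdf = cell.df.set_index(["chrom", "pos"])
    cdf = cdf[~cdf.index.duplicated()]
    joined = ref_sites.set_index(["chrom", "pos"]).join(
        cdf[["gt", "depth", "alt_reads"]], rsuffix="_cell")
    return joined.reset_index()


# ---------------------------------------------------------------------------
# Allelic dropout
# ---------------------------------------------------------------------------

def allelic_dropout_rate(cells: list[CellCallSet], ref: PopulationReference,
                         min_depth: int = 6, restricted: bool = True
                         ) -> RateEstimate:
    """Mean fraction of reference-het sites called homozygous per cell.

    restricted=True: both samples need depth >= ``min_depth`` and the cell
    must be genotyped. restricted=False: all reference-het sites count and
    an uncalled cell site is a dropout event.
    Cells with zero qualifying sites are excluded from the mean (logged).
    """
    het = ref.het_sites()[["chrom", "pos", "depth"]].rename(columns={"depth": "ref_depth"})
    per_cell: dict[str, float] = {}
    for cell in cells:
        j = _cell_at_ref_sites(het, cell)
        genotyped = j["gt"].notna()
        hom = j["gt"].isin((HOM_REF, HOM_ALT))
        if restricted:
            qualifying = (genotyped & (j["ref_depth"] >= min_depth)
                          & (j["depth"].fillna(0) >= min_depth))
            dropout = qualifying & hom
        else:
            qualifying = pd.Series(True, index=j.index)
            dropout = hom | ~genotyped
        denom = int(qualifying.sum())
        if denom == 0:
            log.warning("cell %s: no qualifying het sites; ADR undefined", cell.cell_id)
            continue
        per_cell[cell.cell_id] = float((dropout & qualifying).sum()) / denom
    return _summarize(per_cell)


def ado_allele_bias(cells: list[CellCallSet], ref: PopulationReference) -> float:
    """Among dropout calls (reference het, cell hom), the fraction that are
    hom_alt — i.e. AB -> BB events (reference-allele loss)."""
    het = ref.het_sites()[["chrom", "pos"]]
    n_bb = n_total = 0
    for cell in cells:
        j = _cell_at_ref_sites(het, cell)
        hom = j["gt"].isin((HOM_REF, HOM_ALT))
        n_total += int(hom.sum())
        n_bb += int((j["gt"] == HOM_ALT).sum())
    if n_total == 0:
        return float("nan")
    return n_bb / n_total


def ado_event_sites(cells: list[CellCallSet], ref: PopulationReference
                    ) -> list[set[tuple[str, int]]]:
    """Per-cell sets of (chrom, pos) dropout sites (for recurrence analysis)."""
    het = ref.het_sites()[["chrom", "pos"]]
    out = []
    for cell in cells:
        j = _cell_at_ref_sites(het, cell)
        hom = j["gt"].isin((HOM_REF, HOM_ALT))
        out.append(set(zip(j.loc[hom, "chrom"], j.loc[hom, "pos"])))
    return out


# ---------------------------------------------------------------------------
# False positives
# ---------------------------------------------------------------------------

def _fp_calls(cell: CellCallSet, ref: PopulationReference) -> pd.DataFrame:
    """SNV het calls at sites that are hom-ref (or absent, hence hom-ref)
    in the population reference."""
    variant_pos = set(zip(ref.variant_sites()["chrom"], ref.variant_sites()["pos"]))
    df = cell.df
    het_snv = (df["gt"] == HET) & (df["vtype"] == SNV)
    keys = list(zip(df["chrom"], df["pos"]))
    at_ref_variant = np.array([k in variant_pos for k in keys], dtype=bool)
    return df[het_snv & ~at_ref_variant]


def false_positive_rate(cells: list[CellCallSet], ref: PopulationReference,
                        min_depth: int = 6) -> RateEstimate:
    """Per-cell het-call rate at population hom-ref sites.

    The denominator is the cell's ``hom_ref_callable_bp`` when recorded
    (number of hom-ref target bases with cell depth >= 6); otherwise it
    falls back to the hom-ref records present in the reference with depth
    >= ``min_depth`` in both samples — the right denominator for small
    hand-built call sets where every site is an explicit record.
    """
    hom_ref_records = ref.df[ref.df["gt"] == HOM_REF][["chrom", "pos", "depth"]]
    per_cell: dict[str, float] = {}
    for cell in cells:
        fp = _fp_calls(cell, ref)
        numer = int((fp["depth"] >= min_depth).sum())
        if cell.hom_ref_callable_bp is not None:
            denom = int(cell.hom_ref_callable_bp)
        else:
            j = _cell_at_ref_sites(
                hom_ref_records.rename(columns={"depth": "ref_depth"}), cell)
            denom = int(((j["ref_depth"] >= min_depth)
                         & (j["depth"].fillna(0) >= min_depth)).sum())
        if denom == 0:
            log.warning("cell %s: no qualifying hom-ref sites; FPR undefined",
                        cell.cell_id)
            continue
        per_cell[cell.cell_id] = numer / denom
    return _summarize(per_cell)


@dataclass
class SpectrumReport:
    """Counts of FP calls over the 12 directional substitution classes."""

    counts: dict[str, int]
    transition_fraction: float | None  # combined C>T + G>A mass; None if no FPs

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def fp_spectrum(cells: list[CellCallSet], ref: PopulationReference) -> SpectrumReport:
    """Classify every FP call by its directional substitution (ref>alt)."""
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    for cell in cells:
        fp = _fp_calls(cell, ref)
        for r, a in zip(fp["ref"], fp["alt"]):
            cls = f"{r}>{a}"
            if cls in counts:
                counts[cls] += 1
    total = sum(counts.values())
    frac = (sum(counts[c] for c in TRANSITION_CLASSES) / total) if total else None
    return SpectrumReport(counts, frac)


def fp_event_sites(cells: list[CellCallSet], ref: PopulationReference
                   ) -> list[set[tuple[str, int]]]:
    """Per-cell sets of (chrom, pos) FP sites (for recurrence analysis)."""
    return [set(zip(f["chrom"], f["pos"]))
            for f in (_fp_calls(c, ref) for c in cells)]


# ---------------------------------------------------------------------------
# Recurrence and consensus mitigation
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceReport:
    fraction_recurrent: float
    mean_cells_per_recurrent_site: float
    n_sites: int = 0
    n_recurrent: int = 0


def recurrence_analysis(event_sites_per_cell: list[set], n_cells: int | None = None
                        ) -> RecurrenceReport:
    """How often the same event site appears in two or more cells.

    A site is recurrent iff it occurs in >= 2 cells' event sets;
    multiplicity is the number of cells sharing it.
    """
    multiplicity: dict = {}
    for sites in event_sites_per_cell:
        for s in sites:
            multiplicity[s] = multiplicity.get(s, 0) + 1
    if not multiplicity:
        return RecurrenceReport(0.0, 0.0, 0, 0)
    counts = np.array(list(multiplicity.values()))
    recurrent = counts >= 2
    frac = float(recurrent.mean())
    mean_mult = float(counts[recurrent].mean()) if recurrent.any() else 0.0
    return RecurrenceReport(frac, mean_mult, int(counts.size), int(recurrent.sum()))


def consensus_fp_rate(p: float, n: int) -> float:
    """Probability that the same (independent, uniform) FP appears in all of
    ``n`` cells: p**n. Calling variants in two or more cells therefore
    suppresses FPs multiplicatively."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(p) ** int(n)


def errors_per_megabase(p: float) -> float:
    """Convert a per-base error rate to errors per megabase."""
    return float(p) * 1e6


def compare_with_truth(report: "ErrorReport", truth: pd.DataFrame,
                       ref: PopulationReference, n_cells: int) -> dict:
    """Estimator-vs-truth comparison for simulated data.

    ``truth`` is the generator's event table (chrom, pos, cell_id, event).
    Returns injected event counts, the injected dropout rate implied by the
    reference's het sites, and the estimator outputs side by side.
    """
    counts = truth["event"].value_counts().to_dict()
    n_het = len(ref.het_sites())
    ado_events = counts.get("ado_to_AA", 0) + counts.get("ado_to_BB", 0)
    injected_ado_rate = (ado_events / (n_cells * n_het)) if n_het else None
    injected_bias = (counts.get("ado_to_BB", 0) / ado_events) if ado_events else None
    return {
        "truth_event_counts": counts,
        "injected_ado_rate": injected_ado_rate,
        "injected_ado_bb_bias": injected_bias,
        "estimated_adr_restricted": report.adr_restricted.mean,
        "estimated_adr_unrestricted": report.adr_unrestricted.mean,
        "estimated_ado_bb_bias": report.ado_bias,
        "truth_fp_events": counts.get("fp_injected", 0),
        "estimated_fpr": report.fpr.mean,
    }


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    adr_restricted: RateEstimate
    adr_unrestricted: RateEstimate
    fpr: RateEstimate
    spectrum: SpectrumReport
    ado_bias: float
    fp_recurrence: RecurrenceReport
    ado_recurrence: RecurrenceReport
    consensus_fp_two_cells: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "adr_restricted": {"per_cell": self.adr_restricted.per_cell,
                               "mean": self.adr_restricted.mean,
                               "sem": self.adr_restricted.sem},
            "adr_unrestricted": {"per_cell": self.adr_unrestricted.per_cell,
                                 "mean": self.adr_unrestricted.mean,
                                 "sem": self.adr_unrestricted.sem},
            "fpr": {"per_cell": self.fpr.per_cell, "mean": self.fpr.mean,
                    "sem": self.fpr.sem},
            "fp_spectrum": self.spectrum.counts,
            "fp_transition_fraction": self.spectrum.transition_fraction,
            "ado_bias_bb_fraction": self.ado_bias,
            "fp_recurrence": vars(self.fp_recurrence),
            "ado_recurrence": vars(self.ado_recurrence),
            "consensus_fp_two_cells": self.consensus_fp_two_cells,
        }


def error_report(cells: list[CellCallSet], ref: PopulationReference,
                 min_depth: int = 6) -> ErrorReport:
    """Compute the full error section on (already filtered) call sets."""
    fpr = false_positive_rate(cells, ref, min_depth=min_depth)
    return ErrorReport(
        adr_restricted=allelic_dropout_rate(cells, ref, min_depth, restricted=True),
        adr_unrestricted=allelic_dropout_rate(cells, ref, min_depth, restricted=False),
        fpr=fpr,
        spectrum=fp_spectrum(cells, ref),
        ado_bias=ado_allele_bias(cells, ref),
        fp_recurrence=recurrence_analysis(fp_event_sites(cells, ref)),
        ado_recurrence=recurrence_analysis(ado_event_sites(cells, ref)),
        consensus_fp_two_cells=(consensus_fp_rate(fpr.mean, 2)
                                if np.isfinite(fpr.mean) else float("nan")),
    )
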