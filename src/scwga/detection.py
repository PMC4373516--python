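"""Variant detection efficiency: bulk variants recovered per single cell.

A population variant is *detected* in a cell when the bulk genotype is AB
and the cell is called AB or BB — a cell that lost the reference allele
still carries (and reports) the variant. Bulk BB sites count as detected
when the cell call is AB or BB as well; this extends the AB-site rule to
hom-alt reference variants and is flagged in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import HET, HOM_ALT, CellCallSet, PopulationReference
from .errors import RateEstimate, _cell_at_ref_sites, _summarize

log = logging.getLogger(__name__)


@dataclass
class DetectionReport:
    variant_type: str | None        # "SNV", "indel", or None for both
    restricted: bool                # True: denominator needs cell depth >= min_depth
    min_depth: int
    per_cell_detected: dict[str, int]
    per_cell_total: dict[str, int]
    efficiency: RateEstimate
    includes_hom_alt_reference_sites: bool = True

    @property
    def pooled_detected(self) -> int:
        return sum(self.per_cell_detected.values())

    @property
    def pooled_total(self) -> int:
        return sum(self.per_cell_total.values())

    @property
    def pooled_efficiency(self) -> float:
        """Aggregate-count summary (sum detected / sum total); generally not
        identical to the mean of per-cell ratios."""
        return self.pooled_detected / self.pooled_total if self.pooled_total else float("nan")

    def to_dict(self) -> dict:
        return {
            "variant_type": self.variant_type,
            "restricted": self.restricted,
            "per_cell_detected": self.per_cell_detected,
            "per_cell_total": self.per_cell_total,
            "mean_efficiency": self.efficiency.mean,
            "sem": self.efficiency.sem,
            "pooled_detected": self.pooled_detected,
            "pooled_total": self.pooled_total,
            "pooled_efficiency": self.pooled_efficiency,
            "includes_hom_alt_reference_sites": self.includes_hom_alt_reference_sites,
        }


def detection_efficiency(ref: PopulationReference, cells: list[CellCallSet],
                         variant_type: str | None = None, min_depth: int = 6,
                         restricted: bool = True) -> DetectionReport:
    """Per-cell and mean fraction of reference variants seen in each cell.

    restricted=True: the per-cell denominator is the reference variant
    sites at which the cell has depth >= ``min_depth`` (sufficient coverage
    to call); restricted=False uses every reference variant site regardless
    of coverage. Zero-denominator cells are excluded from the mean.
    """
    sites = ref.variant_sites()
    if variant_type is not None:
        sites = sites[sites["vtype"] == variant_type]
    sites = sites[["chrom", "pos"]]
    detected: dict[str, int] = {}
    totals: dict[str, int] = {}
    ratios: dict[str, float] = {}
    for cell in cells:
        j = _cell_at_ref_sites(sites, cell)
        carries = j["gt"].isin((HET, HOM_ALT))
        if restricted:
            eligible = j["depth"].fillna(0) >= min_depth
        else:
            eligible = np.ones(len(j), dtype=bool)
        total = int(np.asarray(eligible).sum())
        hits = int((carries & eligible).sum())
        if total == 0:
            log.warning("cell %s: no eligible variant sites; detection efficiency "
                        "undefined", cell.cell_id)
            continue
        detected[cell.cell_id] = hits
        totals[cell.cell_id] = total
        ratios[cell.cell_id] = hits / total
    return DetectionReport(variant_type, restricted, min_depth,
                           detected, totals, _summarize(ratios))
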