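"""Post-calling site filters and the SNV/indel partition.

Mirrors the post-alignment portion of a joint-calling pipeline: mapping
quality >= 40, minimum base quality 20 (carried as a per-record pass flag,
since base-level filtering happens inside the caller), minimum depth 6,
>= 2 variant-supporting reads, and removal of SNV clusters within 10 bp
(an FP-dense-region heuristic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HET, HOM_ALT, HOM_REF, SNV, CellCallSet, PopulationReference

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_mq: int = 40
    min_base_quality: int = 20  # documented threshold behind the bq_pass flag
    min_depth: int = 6
    min_alt_reads: int = 2
    cluster_window_bp: int = 10
    alt_read_filter_indels: bool = True

    def __post_init__(self):
        for name in ("min_mq", "min_base_quality", "min_depth",
                     "min_alt_reads", "cluster_window_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def apply_site_filters(calls: CellCallSet, config: FilterConfig | None = None
                       ) -> CellCallSet:
    """Threshold filters, applied per site (order-independent).

    A record is retained iff MQ >= min_mq AND depth >= min_depth AND, for
    variant (non-hom_ref) calls, the base-quality flag passes AND
    alt_reads >= min_alt_reads. hom_ref records are judged on depth/MQ only.
    Each removed record is tagged with the first failing filter; the tags
    are attached to the returned call set (``filter_tags``).
    """
    config = config or FilterConfig()
    df = calls.df
    is_variant = df["gt"].isin((HET, HOM_ALT)).to_numpy()
    alt_rule = is_variant
    if not config.alt_read_filter_indels:
        alt_rule = is_variant & (df["vtype"] == SNV).to_numpy()

    tags = np.full(len(df), "PASS", dtype=object)
    fail_mq = df["mq"].to_numpy() < config.min_mq
    fail_bq = is_variant & ~df["bq_pass"].to_numpy()
    fail_depth = df["depth"].to_numpy() < config.min_depth
    fail_alt = alt_rule & (df["alt_reads"].to_numpy() < config.min_alt_reads)
    for name, mask in (("MQ", fail_mq), ("BQ", fail_bq),
                       ("DEPTH", fail_depth), ("ALT_READS", fail_alt)):
        tags[(tags == "PASS") & mask] = name

    keep = tags == "PASS"
    out = CellCallSet(df[keep], cell_id=calls.cell_id,
                      hom_ref_callable_bp=calls.hom_ref_callable_bp)
    out.filter_tags = pd.Series(tags, index=df.index, name="filter_tag")
    return out


def filter_clustered_snvs(calls: CellCallSet, window_bp: int = 10) -> CellCallSet:
    """Remove every SNV call that has another SNV call within ``window_bp``
    on the same chromosome (all cluster members go; indels and hom_ref
    records neither trigger nor suffer removal)."""
    df = calls.df
    is_snv_call = ((df["vtype"] == SNV) & df["gt"].isin((HET, HOM_ALT))).to_numpy()
    remove = np.zeros(len(df), dtype=bool)
    for chrom, grp in df[is_snv_call].groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()  # already sorted
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        near_prev = np.concatenate(([False], gaps <= window_bp))
        near_next = np.concatenate((gaps <= window_bp, [False]))
        remove[grp.index.to_numpy()[near_prev | near_next]] = True
    out = CellCallSet(df[~remove], cell_id=calls.cell_id,
                      hom_ref_callable_bp=calls.hom_ref_callable_bp)
    out.filter_tags = calls.filter_tags
    return out


def partition_variants(calls: CellCallSet) -> tuple[CellCallSet, CellCallSet]:
    """Disjoint, exhaustive split of records by variant type of the site."""
    df = calls.df
    snv = CellCallSet(df[df["vtype"] == SNV], cell_id=calls.cell_id,
                      hom_ref_callable_bp=calls.hom_ref_callable_bp)
    indel = CellCallSet(df[df["vtype"] != SNV], cell_id=calls.cell_id,
                        hom_ref_callable_bp=calls.hom_ref_callable_bp)
    return snv, indel


def build_presence_matrix(ref: PopulationReference, cells: list[CellCallSet],
                          min_depth: int = 6
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary presence strings over the reference's variant sites.

    Returns ``(presence, callable_mask)``, both indexed by (chrom, pos) with
    columns [reference sample] + cell ids. ``presence`` is 1 where the
    sample carries the non-reference allele (het or hom_alt);
    ``callable_mask`` is True where the sample's depth >= ``min_depth``
    (absent records count as depth 0).
    """
    sites = ref.variant_sites().set_index(["chrom", "pos"])
    idx = sites.index
    presence = pd.DataFrame(index=idx)
    callable_ = pd.DataFrame(index=idx)
    presence[ref.sample_id] = 1
    callable_[ref.sample_id] = sites["depth"] >= min_depth
    for cell in cells:
        cdf = cell.df.set_index(["chrom", "pos"])
        cdf = cdf[~cdf.index.duplicated()]
        sub = cdf.reindex(idx)
        presence[cell.cell_id] = sub["gt"].isin((HET, HOM_ALT)).astype(int).to_numpy()
        callable_[cell.cell_id] = (sub["depth"].fillna(0) >= min_depth).to_numpy()
    return presence, callable_
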