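"""Containers and readers/writers for the formats the pipeline touches.

Coordinate conventions are strict and converted only at the I/O boundary:
variant positions are 1-based (VCF convention); intervals are 0-based
half-open (BED/bedGraph convention).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# genotype classes
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
GENOTYPES = (HOM_REF, HET, HOM_ALT)

# variant types
SNV = "SNV"
INDEL = "indel"

REF_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "gt", "depth", "mq"]
CELL_COLUMNS = REF_COLUMNS + ["alt_reads", "bq_pass"]


class FormatError(ValueError):
    """Raised on malformed input files."""


def classify_variant(ref: str, alt: str) -> str:
    """SNV iff both alleles have length 1, else indel."""
    return SNV if len(ref) == 1 and len(alt) == 1 else INDEL


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Target regions (BED)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetRegion:
    """Sorted, non-overlapping 0-based half-open intervals."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        prev: dict[str, int] = {}
        for chrom, start, end in self.intervals:
            if end <= start or start < 0:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            if chrom in prev and start < prev[chrom]:
                raise ValueError("intervals must be sorted and non-overlapping; "
                                 "use TargetRegion.from_intervals to normalize")
            prev[chrom] = end

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "TargetRegion":
        """Build a region, sorting and merging overlapping/adjacent-overlap
        intervals (merges are logged)."""
        by_chrom: dict[str, list[list[int]]] = {}
        order: list[str] = []
        for chrom, start, end in intervals:
            if chrom not in by_chrom:
                by_chrom[chrom] = []
                order.append(chrom)
            by_chrom[chrom].append([int(start), int(end)])
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted(order):
            ivs = sorted(by_chrom[chrom])
            cur = ivs[0]
            for s, e in ivs[1:]:
                if s < cur[1]:
                    log.warning("merging overlapping intervals on %s: [%d,%d) and [%d,%d)",
                                chrom, cur[0], cur[1], s, e)
                    cur[1] = max(cur[1], e)
                else:
                    merged.append((chrom, cur[0], cur[1]))
                    cur = [s, e]
            merged.append((chrom, cur[0], cur[1]))
        return cls(tuple(merged))

    @property
    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    @property
    def chroms(self) -> tuple[str, ...]:
        seen = dict.fromkeys(c for c, _, _ in self.intervals)
        return tuple(seen)

    def chrom_intervals(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.intervals if c == chrom]

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return any(s < pos <= e for s, e in self.chrom_intervals(chrom))


def read_bed(path) -> TargetRegion:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    if df.empty:
        raise FormatError(f"empty BED file: {path}")
    return TargetRegion.from_intervals(df.itertuples(index=False, name=None))


def write_bed(region: TargetRegion, path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, start, end in region.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Depth profiles (bedGraph)
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Run-length-encoded per-base depth covering a target region exactly.

    ``runs`` has columns chrom, start, end (0-based half-open) and depth;
    the runs tile the region with no gaps or overlap.
    """

    region: TargetRegion
    runs: pd.DataFrame

    @classmethod
    def from_per_base(cls, region: TargetRegion,
                      depths_by_chrom: dict[str, np.ndarray]) -> "DepthProfile":
        """Build from one concatenated per-base array per chromosome (in
        target order over that chromosome's intervals)."""
        frames = []
        for chrom in region.chroms:
            arr = np.asarray(depths_by_chrom[chrom])
            offset = 0
            for start, end in region.chrom_intervals(chrom):
                n = end - start
                seg = arr[offset:offset + n]
                if seg.size != n:
                    raise ValueError(f"depth array for {chrom} does not cover the target")
                offset += n
                # RLE within the interval
                change = np.flatnonzero(np.diff(seg)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [n]))
                frames.append(pd.DataFrame({
                    "chrom": chrom,
                    "start": start + starts,
                    "end": start + ends,
                    "depth": seg[starts].astype(np.int64),
                }))
            if offset != arr.size:
                raise ValueError(f"depth array for {chrom} longer than the target")
        runs = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["chrom", "start", "end", "depth"]))
        return cls(region, runs)

    def per_base(self, chrom: str) -> np.ndarray:
        """Per-base depths over this chromosome's target intervals, concatenated."""
        sub = self.runs[self.runs["chrom"] == chrom]
        return np.repeat(sub["depth"].to_numpy(),
                         (sub["end"] - sub["start"]).to_numpy())

    def all_depths(self) -> np.ndarray:
        """Per-base depths over the whole target (region order)."""
        return np.repeat(self.runs["depth"].to_numpy(),
                         (self.runs["end"] - self.runs["start"]).to_numpy())

    def depth_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Depth at 1-based positions (must fall inside the target)."""
        per_base = self.per_base(chrom)
        # map genomic position -> offset within concatenated target bases
        offsets = np.empty(len(positions), dtype=np.int64)
        positions = np.asarray(positions)
        cum = 0
        remaining = np.ones(len(positions), dtype=bool)
        for start, end in self.region.chrom_intervals(chrom):
            inside = remaining & (positions > start) & (positions <= end)
            offsets[inside] = cum + (positions[inside] - 1 - start)
            remaining &= ~inside
            cum += end - start
        if remaining.any():
            bad = positions[remaining][0]
            raise ValueError(f"position {chrom}:{bad} outside the target region")
        return per_base[offsets]

    @property
    def total_read_mass(self) -> int:
        lengths = (self.runs["end"] - self.runs["start"]).to_numpy()
        return int((self.runs["depth"].to_numpy() * lengths).sum())


def write_bedgraph(profile: DepthProfile, path) -> None:
    """Write non-zero runs; zero-depth bases are implied by gaps."""
    nz = profile.runs[profile.runs["depth"] > 0]
    nz.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, region: TargetRegion) -> DepthProfile:
    """Read a bedGraph over a target region; bases absent from the file
    (gaps) are read as depth 0."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "depth"],
                     dtype={"chrom": str, "start": np.int64,
                            "end": np.int64, "depth": np.int64})
    depths = {}
    for chrom in region.chroms:
        n = sum(e - s for s, e in region.chrom_intervals(chrom))
        arr = np.zeros(n, dtype=np.int64)
        offset = 0
        sub = df[df["chrom"] == chrom]
        for start, end in region.chrom_intervals(chrom):
            hit = sub[(sub["end"] > start) & (sub["start"] < end)]
            s = np.clip(hit["start"].to_numpy(), start, end) - start
            e = np.clip(hit["end"].to_numpy(), start, end) - start
            lengths = e - s
            if lengths.sum():
                # scatter each run's depth over its bases, fully vectorized
                run_offsets = np.cumsum(lengths) - lengths
                idx = (np.repeat(s, lengths) + np.arange(lengths.sum())
                       - np.repeat(run_offsets, lengths))
                arr[offset + idx] = np.repeat(hit["depth"].to_numpy(), lengths)
            offset += end - start
        depths[chrom] = arr
    return DepthProfile.from_per_base(region, depths)


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------

def _prepare_calls(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    df = df[list(columns)].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["depth"] = df["depth"].astype(np.int64)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


@dataclass
class PopulationReference:
    """Bulk-sample truth set: one record per site with a genotype call.

    Variant sites carry gt het/hom_alt; hom_ref records appear only where
    some cell has a (false-positive) variant, mirroring a joint-called VCF.
    """

    df: pd.DataFrame
    sample_id: str = "population"

    def __post_init__(self):
        self.df = _prepare_calls(self.df, REF_COLUMNS)
        if (self.df["depth"] < 0).any():
            raise ValueError("reference depths must be >= 0")

    def het_sites(self) -> pd.DataFrame:
        return self.df[self.df["gt"] == HET]

    def variant_sites(self) -> pd.DataFrame:
        return self.df[self.df["gt"].isin((HET, HOM_ALT))]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CellCallSet:
    """One single cell's call set.

    ``hom_ref_callable_bp`` — number of target bases that are homozygous
    reference in the population sample and have cell depth >= 6; a VCF does
    not contain these sites, so the simulator records the count explicitly
    for use as the false-positive-rate denominator.
    """

    df: pd.DataFrame
    cell_id: str = "cell"
    hom_ref_callable_bp: int | None = None
    filter_tags: pd.Series | None = None

    def __post_init__(self):
        self.df = _prepare_calls(self.df, CELL_COLUMNS)
        self.df["alt_reads"] = self.df["alt_reads"].astype(np.int64)
        self.df["bq_pass"] = self.df["bq_pass"].astype(bool)
        if (self.df["alt_reads"] > self.df["depth"]).any():
            raise ValueError("alt_reads cannot exceed depth")

    def variant_sites(self) -> pd.DataFrame:
        return self.df[self.df["gt"].isin((HET, HOM_ALT))]

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# QC matrix
# ---------------------------------------------------------------------------

N_QC_AMPLICONS = 22


@dataclass
class QCMatrix:
    """Cells x amplicons boolean amplification-success table."""

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    amplicon_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("QC matrix must be 2-D")
        n_cells, n_amp = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n_cells)]
        if not self.amplicon_ids:
            self.amplicon_ids = [f"amp{i + 1:02d}" for i in range(n_amp)]
        if len(self.cell_ids) != n_cells or len(self.amplicon_ids) != n_amp:
            raise ValueError("id lists do not match matrix shape")
        if n_amp != N_QC_AMPLICONS:
            raise ValueError(f"QC panel must have {N_QC_AMPLICONS} amplicons, got {n_amp}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def positives_per_cell(self) -> np.ndarray:
        return self.values.sum(axis=1)


def write_qc_tsv(qc: QCMatrix, path) -> None:
    pd.DataFrame(qc.values.astype(int), index=qc.cell_ids,
                 columns=qc.amplicon_ids).to_csv(path, sep="\t", index_label="cell")


def read_qc_tsv(path) -> QCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return QCMatrix(df.to_numpy(dtype=bool).astype(bool),
                    cell_ids=[str(c) for c in df.index],
                    amplicon_ids=[str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TO_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}
_STRING_TO_GT = {"0/0": HOM_REF, "0/1": HET, "1/0": HET, "1/1": HOM_ALT}

_VCF_HEADER_LINES = [
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality of the population reference sample">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">',
    '##FORMAT=<ID=MQ,Number=1,Type=Integer,Description="Per-sample mapping quality">',
    '##FORMAT=<ID=BQ,Number=1,Type=Integer,Description="1 if the record passes the minimum-base-quality criterion">',
]


def write_vcf(path, ref: PopulationReference, cells: Sequence[CellCallSet],
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a multi-sample VCF 4.2 (sample 0 = population reference).

    Sites are keyed by (chrom, pos, ref, alt); a sample without a record at
    a site is emitted as a no-call (``./.``).
    """
    key = ["chrom", "pos", "ref", "alt"]
    sites = pd.concat([f[key] for f in [ref.df] + [c.df for c in cells]])
    sites = sites.drop_duplicates().sort_values(["chrom", "pos", "ref", "alt"],
                                                kind="mergesort")
    sites = sites.reset_index(drop=True)

    ref_lookup = ref.df.set_index(key)
    cell_lookups = [c.df.set_index(key) for c in cells]

    if contig_lengths is None:
        contig_lengths = {c: int(g["pos"].max()) + 1000
                          for c, g in sites.groupby("chrom")}

    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=scwga\n")
        for chrom, length in sorted(contig_lengths.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        samples = [ref.sample_id] + [c.cell_id for c in cells]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for row in sites.itertuples(index=False):
            k = (row.chrom, row.pos, row.ref, row.alt)
            try:
                r = ref_lookup.loc[k]
                info = f"MQ={int(r['mq'])}"
                ref_field = (f"{_GT_TO_STRING[r['gt']]}:{int(r['depth'])}:"
                             f"{int(r['depth']) if r['gt'] == HOM_REF else 0},0:"
                             f"{int(r['mq'])}:1")
                if r["gt"] != HOM_REF:
                    dp = int(r["depth"])
                    # reference sample read support consistent with its genotype
                    alt_n = dp // 2 if r["gt"] == HET else dp
                    ref_field = (f"{_GT_TO_STRING[r['gt']]}:{dp}:{dp - alt_n},{alt_n}:"
                                 f"{int(r['mq'])}:1")
            except KeyError:
                info = "."
                ref_field = "./.:.:.,.:.:."
            fields = [ref_field]
            for lookup in cell_lookups:
                try:
                    c = lookup.loc[k]
                    dp = int(c["depth"])
                    alt_n = int(c["alt_reads"])
                    fields.append(f"{_GT_TO_STRING[c['gt']]}:{dp}:{dp - alt_n},{alt_n}:"
                                  f"{int(c['mq'])}:{int(bool(c['bq_pass']))}")
                except KeyError:
                    fields.append("./.:.:.,.:.:.")
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                     f"{info}\tGT:DP:AD:MQ:BQ\t" + "\t".join(fields) + "\n")


def read_multisample_vcf(path, reference_sample_id: str = "population"
                         ) -> tuple[PopulationReference, list[CellCallSet]]:
    """Read a joint-called VCF into a reference truth set plus one call set
    per remaining sample. Missing genotypes (./.) become no-calls (the site
    is simply absent from that sample's records)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if reference_sample_id not in samples:
        raise FormatError(f"reference sample {reference_sample_id!r} not in VCF "
                          f"(samples: {samples})")
    ref_idx = samples.index(reference_sample_id)
    cell_idx = [i for i in range(len(samples)) if i != ref_idx]

    ref_rows = []
    cell_rows: dict[int, list] = {i: [] for i in cell_idx}
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FormatError(f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                              "is not supported")
        alt = variant.ALT[0]
        vtype = classify_variant(variant.REF, alt)
        dp = variant.format("DP")
        ad = variant.format("AD")
        mq = variant.format("MQ")
        bq = variant.format("BQ")
        gts = variant.genotypes  # [allele_a, allele_b, phased]
        for i in range(len(samples)):
            a, b = gts[i][0], gts[i][1]
            if a < 0 or b < 0:
                continue  # no-call
            gt = (HOM_REF, HET)[a + b] if a + b < 2 else HOM_ALT
            depth = int(dp[i][0]) if dp is not None and dp[i][0] >= 0 else 0
            site_mq = int(mq[i][0]) if mq is not None and mq[i][0] >= 0 else 60
            if i == ref_idx:
                ref_rows.append((variant.CHROM, variant.POS, variant.REF, alt,
                                 vtype, gt, depth, site_mq))
            else:
                alt_reads = int(ad[i][1]) if ad is not None and ad[i][1] >= 0 else 0
                bq_pass = bool(bq[i][0]) if bq is not None and bq[i][0] >= 0 else True
                cell_rows[i].append((variant.CHROM, variant.POS, variant.REF, alt,
                                     vtype, gt, depth, site_mq,
                                     min(alt_reads, depth), bq_pass))
    ref = PopulationReference(pd.DataFrame(ref_rows, columns=REF_COLUMNS),
                              sample_id=reference_sample_id)
    cells = [CellCallSet(pd.DataFrame(cell_rows[i], columns=CELL_COLUMNS),
                         cell_id=samples[i]) for i in cell_idx]
    return ref, cells


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["chrom", "pos", "cell_id", "event"]
TRUTH_EVENTS = ("ado_to_AA", "ado_to_BB", "fp_injected")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64,
                                              "cell_id": str, "event": str})
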