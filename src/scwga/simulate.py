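"""Seeded generator of single-cell WGA exome experiments.

The generator produces the full object graph a real experiment would yield
after joint variant calling: a deeply sequenced diploid population reference
over an exome-like target, per-cell over-dispersed depth tracks, per-cell
call sets carrying allelic-dropout and false-positive artifacts with ground
truth, and qPCR-panel QC tables.

Error model
-----------
* Allelic dropout acts at call level: at each reference-het site a cell's
  genotype flips to hom with probability ``d`` (elevated at a shared set of
  hotspot sites), to BB with probability ``beta`` else AA. Read evidence
  (depth, alt count) is drawn consistently with the *called* genotype.
* False positives are spurious het calls at homozygous-reference bases,
  injected per cell at ``fp_rate`` with substitution classes drawn from a
  transition-skewed spectrum. FP and dropout events are only recorded where
  the cell has at least one read, since an uncovered base yields no call.
* Per-base depth is zero-inflated gamma-Poisson (negative binomial); the
  zero mass models uncaptured or unamplified regions and directly sets
  coverage breadth.

Determinism: every stream derives from ``config.seed`` plus a fixed stream
id, so outputs are byte-identical across runs and independent of the order
in which cells are generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SUBSTITUTION_CLASSES, ConfigurationError, SimulationConfig
from .io import (CELL_COLUMNS, HET, HOM_ALT, HOM_REF, INDEL, REF_COLUMNS, SNV,
                 TRUTH_COLUMNS, CellCallSet, DepthProfile, PopulationReference,
                 QCMatrix, TargetRegion)

# fixed stream ids (offsets under the master seed)
_STREAM_REFERENCE = 1
_STREAM_HOTSPOTS = 2
_STREAM_REF_FP_DEPTH = 3
_STREAM_QC = 4
_STREAM_DEPTH_BASE = 1_000
_STREAM_CALLS_BASE = 2_000

_BASES = np.array(["A", "C", "G", "T"])


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def target_region(config: SimulationConfig) -> TargetRegion:
    """The simulated capture target: a single contiguous interval."""
    return TargetRegion(((config.chrom, 0, config.target_size_bp),))


# ---------------------------------------------------------------------------
# Population reference
# ---------------------------------------------------------------------------

def simulate_population_reference(config: SimulationConfig) -> PopulationReference:
    """Place the configured het/hom SNVs and indels uniformly at random
    (without positional collision) on the target.

    Every site carries depth >= 6 so the reference is fully callable,
    mirroring a deeply sequenced (~59X) bulk sample.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_REFERENCE)
    n = config.n_variants
    if n == 0:
        return PopulationReference(pd.DataFrame(columns=REF_COLUMNS))
    positions = np.sort(rng.choice(config.target_size_bp, size=n, replace=False)) + 1

    labels = np.repeat(
        np.arange(4),
        [config.n_het_snvs, config.n_hom_snvs, config.n_het_indels, config.n_hom_indels],
    )
    rng.shuffle(labels)
    is_snv = labels < 2
    gt = np.where((labels == 0) | (labels == 2), HET, HOM_ALT)

    ref_base = _BASES[rng.integers(0, 4, size=n)]
    # SNV alt: a different base; indel: 1-bp insertion or deletion
    alt_shift = rng.integers(1, 4, size=n)
    base_idx = np.searchsorted(_BASES, ref_base)
    snv_alt = _BASES[(base_idx + alt_shift) % 4]
    extra = _BASES[rng.integers(0, 4, size=n)]
    is_insertion = rng.random(n) < 0.5

    ref_allele = np.where(is_snv, ref_base,
                          np.where(is_insertion, ref_base,
                                   np.char.add(ref_base, extra)))
    alt_allele = np.where(is_snv, snv_alt,
                          np.where(is_insertion, np.char.add(ref_base, extra),
                                   ref_base))

    depth = np.maximum(rng.poisson(config.reference_depth_mean, size=n), 6)
    df = pd.DataFrame({
        "chrom": config.chrom,
        "pos": positions,
        "ref": ref_allele,
        "alt": alt_allele,
        "vtype": np.where(is_snv, SNV, INDEL),
        "gt": gt,
        "depth": depth,
        "mq": 60,
    })
    return PopulationReference(df)


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------

def simulate_depth_profile(config: SimulationConfig, cell_index: int) -> DepthProfile:
    """Per-base depth for one cell: zero-inflated negative binomial.

    The covered component is zero-truncated gamma-Poisson with mean
    ``depth_mean`` and variance ``m + alpha m**2`` before truncation
    (``alpha = depth_dispersion``); ``alpha = 0`` degenerates to constant
    depth. Zero coverage comes only from the ``depth_zero_fraction`` point
    mass, so that parameter is exactly one minus the expected coverage
    breadth.
    """
    config.validate()
    if not 0 <= cell_index < config.n_cells:
        raise ConfigurationError(f"cell_index {cell_index} out of range "
                                 f"(n_cells={config.n_cells})")
    rng = _rng(config.seed, _STREAM_DEPTH_BASE + cell_index)
    n = config.target_size_bp
    alpha = config.depth_dispersion
    if alpha == 0:
        depths = np.full(n, int(round(config.depth_mean)), dtype=np.int64)
    else:
        lam = rng.gamma(shape=1.0 / alpha, scale=config.depth_mean * alpha, size=n)
        depths = rng.poisson(lam).astype(np.int64)
        # zero-truncate the covered component (resample incidental zeros)
        for _ in range(100):
            zero = depths == 0
            if not zero.any():
                break
            lam_z = rng.gamma(shape=1.0 / alpha,
                              scale=config.depth_mean * alpha, size=int(zero.sum()))
            depths[zero] = rng.poisson(lam_z)
        depths[depths == 0] = 1
    if config.depth_zero_fraction > 0:
        depths[rng.random(n) < config.depth_zero_fraction] = 0
    return DepthProfile.from_per_base(target_region(config), {config.chrom: depths})


# ---------------------------------------------------------------------------
# Single-cell call sets
# ---------------------------------------------------------------------------

def ado_hotspot_mask(config: SimulationConfig) -> np.ndarray:
    """Which reference het sites are shared dropout hotspots.

    Derived from the master seed only, so the same sites are hotspots in
    every cell — the mechanism behind recurrent dropout positions.
    """
    n_het = config.n_het_snvs + config.n_het_indels
    rng = _rng(config.seed, _STREAM_HOTSPOTS)
    return rng.random(n_het) < config.ado_hotspot_fraction


def _truncated_binomial_alt(rng, depth: np.ndarray, p: float, floor: np.ndarray
                            ) -> np.ndarray:
    """Alt-read counts ~ Binomial(depth, p), raised to a per-site floor.

    The floor models the fact that a genotype caller only emits a variant
    call when supporting reads exist; called events therefore carry at
    least the caller's evidence minimum.
    """
    alt = rng.binomial(depth, p)
    return np.minimum(np.maximum(alt, floor), depth)


def simulate_single_cell_calls(ref: PopulationReference, depth: DepthProfile,
                               config: SimulationConfig, cell_index: int
                               ) -> tuple[CellCallSet, pd.DataFrame]:
    """Generate one cell's call set plus its ground-truth event table.

    Records are emitted at every reference variant site with cell coverage
    (>= 1 read) — as hom_ref records when the cell shows no variant — and at
    injected FP sites. Uncovered sites yield no record (no-call).
    """
    config.validate()
    region = target_region(config)
    if depth.region != region:
        raise ValueError("depth profile and reference cover different targets")
    if len(ref) and not ref.df["pos"].le(config.target_size_bp).all():
        raise ValueError("reference sites fall outside the configured target")

    rng = _rng(config.seed, _STREAM_CALLS_BASE + cell_index)
    cell_id = f"cell{cell_index}"
    depth_arr = depth.per_base(config.chrom)

    rdf = ref.df
    n_sites = len(rdf)
    site_depth = depth_arr[rdf["pos"].to_numpy() - 1] if n_sites else np.array([], dtype=np.int64)

    gt = rdf["gt"].to_numpy(dtype=object).copy()
    events = np.full(n_sites, "", dtype=object)

    # allelic dropout at het sites (hotspot-adjusted, shared hotspot set)
    het_mask = gt == HET
    n_het = int(het_mask.sum())
    if n_het:
        p_site = np.full(n_het, config.ado_rate)
        hot = ado_hotspot_mask(config)
        if hot.size == n_het:
            p_site[hot] = config.hotspot_ado_rate
        drop = rng.random(n_het) < p_site
        to_bb = rng.random(n_het) < config.ado_bb_bias
        new_gt = np.where(drop, np.where(to_bb, HOM_ALT, HOM_REF), HET)
        gt[het_mask] = new_gt
        ev = np.where(drop, np.where(to_bb, "ado_to_BB", "ado_to_AA"), "")
        events[het_mask] = ev

    # read evidence consistent with the called genotype
    alt_reads = np.zeros(n_sites, dtype=np.int64)
    if n_sites:
        floor2 = np.minimum(site_depth, 2)
        het_call = gt == HET
        hom_alt_call = gt == HOM_ALT
        hom_ref_call = gt == HOM_REF
        alt_reads[het_call] = _truncated_binomial_alt(
            rng, site_depth[het_call], 0.5, floor2[het_call])
        alt_reads[hom_alt_call] = _truncated_binomial_alt(
            rng, site_depth[hom_alt_call], 0.98, floor2[hom_alt_call])
        alt_reads[hom_ref_call] = np.minimum(
            rng.binomial(site_depth[hom_ref_call], 0.005), 1)

    cell = pd.DataFrame({
        "chrom": config.chrom,
        "pos": rdf["pos"].to_numpy() if n_sites else np.array([], dtype=np.int64),
        "ref": rdf["ref"].to_numpy() if n_sites else np.array([], dtype=object),
        "alt": rdf["alt"].to_numpy() if n_sites else np.array([], dtype=object),
        "vtype": rdf["vtype"].to_numpy() if n_sites else np.array([], dtype=object),
        "gt": gt,
        "depth": site_depth,
        "alt_reads": alt_reads,
    })
    truth_pos = cell["pos"].to_numpy()[events != ""] if n_sites else np.array([], dtype=np.int64)
    truth_ev = events[events != ""] if n_sites else np.array([], dtype=object)

    # false positives at homozygous-reference bases
    variant_positions = set(rdf["pos"].tolist())
    n_hom_ref_bases = config.target_size_bp - len(variant_positions)
    n_fp = rng.binomial(n_hom_ref_bases, config.fp_rate) if config.fp_rate > 0 else 0
    fp_positions: list[int] = []
    taken = set(variant_positions)
    while len(fp_positions) < n_fp:
        draw = rng.integers(1, config.target_size_bp + 1,
                            size=max(2 * (n_fp - len(fp_positions)), 16))
        for p in draw:
            p = int(p)
            if p not in taken:
                taken.add(p)
                fp_positions.append(p)
                if len(fp_positions) == n_fp:
                    break
    fp_positions = np.sort(np.array(fp_positions, dtype=np.int64))
    if n_fp:
        fp_depth = depth_arr[fp_positions - 1]
        classes = rng.choice(12, size=n_fp, p=config.fp_spectrum)
        covered = fp_depth >= 1  # an uncovered base cannot produce a call
        fp_positions, fp_depth, classes = (fp_positions[covered], fp_depth[covered],
                                           classes[covered])
        fp_ref = np.array([SUBSTITUTION_CLASSES[c][0] for c in classes], dtype=object)
        fp_alt = np.array([SUBSTITUTION_CLASSES[c][2] for c in classes], dtype=object)
        fp_alt_reads = _truncated_binomial_alt(rng, fp_depth, 0.5,
                                               np.minimum(fp_depth, 2))
        fp_df = pd.DataFrame({
            "chrom": config.chrom, "pos": fp_positions, "ref": fp_ref,
            "alt": fp_alt, "vtype": SNV, "gt": HET,
            "depth": fp_depth, "alt_reads": fp_alt_reads,
        })
        cell = pd.concat([cell, fp_df], ignore_index=True)
        truth_pos = np.concatenate([truth_pos, fp_positions])
        truth_ev = np.concatenate([truth_ev, np.full(len(fp_positions),
                                                     "fp_injected", dtype=object)])

    # quality flags, then drop uncovered sites (no reads -> no call)
    m = len(cell)
    cell["mq"] = np.where(rng.random(m) < config.mq_fail_rate, 25, 60)
    cell["bq_pass"] = rng.random(m) >= config.bq_fail_rate
    covered_mask = cell["depth"].to_numpy() >= 1

    # keep truth rows only for covered (observable) events
    pos_covered = set(cell.loc[covered_mask, "pos"].tolist())
    keep = np.array([int(p) in pos_covered for p in truth_pos], dtype=bool)
    truth = pd.DataFrame({
        "chrom": config.chrom,
        "pos": truth_pos[keep],
        "cell_id": cell_id,
        "event": truth_ev[keep],
    }, columns=TRUTH_COLUMNS)

    cell = cell[covered_mask]

    hom_ref_callable = int((depth_arr >= 6).sum())
    var_pos_arr = rdf["pos"].to_numpy() if n_sites else np.array([], dtype=np.int64)
    if var_pos_arr.size:
        hom_ref_callable -= int((depth_arr[var_pos_arr - 1] >= 6).sum())

    call_set = CellCallSet(cell[CELL_COLUMNS], cell_id=cell_id,
                           hom_ref_callable_bp=hom_ref_callable)
    return call_set, truth


# ---------------------------------------------------------------------------
# QC matrix
# ---------------------------------------------------------------------------

def simulate_qc_matrix(n_cells: int, pass_probabilities, seed: int = 0) -> QCMatrix:
    """Bernoulli qPCR panel outcomes: cell x amplicon success table."""
    p = np.asarray(pass_probabilities, dtype=float)
    if p.shape != (22,):
        raise ConfigurationError(f"expected 22 per-amplicon probabilities, got {p.shape}")
    if ((p < 0) | (p > 1)).any():
        raise ConfigurationError("pass probabilities must lie in [0, 1]")
    rng = _rng(seed, _STREAM_QC)
    return QCMatrix(rng.random((n_cells, 22)) < p)


def qc_matrix_from_counts(n_full: int, n_partial: int, missing_per_partial: int = 1
                          ) -> QCMatrix:
    """Explicit fixture constructor: ``n_full`` cells with 22/22 positive
    amplicons plus ``n_partial`` cells each missing ``missing_per_partial``."""
    rows = [np.ones(22, dtype=bool)] * n_full
    for i in range(n_partial):
        row = np.ones(22, dtype=bool)
        row[np.arange(missing_per_partial) % 22] = False
        rows.append(row)
    return QCMatrix(np.array(rows))


# ---------------------------------------------------------------------------
# Whole experiments
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    """Everything one simulation run produces, plus ground truth."""

    config: SimulationConfig
    target: TargetRegion
    reference: PopulationReference
    cells: list[CellCallSet]
    depth_profiles: list[DepthProfile]
    truth: pd.DataFrame
    qc: QCMatrix | None = None


def simulate_experiment(config: SimulationConfig,
                        qc_pass_probabilities=None) -> SimulatedExperiment:
    """Run the full generator for all cells.

    The returned reference gains hom_ref records at every injected FP site
    (mirroring a joint-called VCF, where such sites appear because some cell
    carries a variant); their depths are drawn from the reference coverage
    model.
    """
    ref = simulate_population_reference(config)
    cells, profiles, truths = [], [], []
    for i in range(config.n_cells):
        profile = simulate_depth_profile(config, i)
        cell, truth = simulate_single_cell_calls(ref, profile, config, i)
        profiles.append(profile)
        cells.append(cell)
        truths.append(truth)
    truth = (pd.concat(truths, ignore_index=True) if truths
             else pd.DataFrame(columns=TRUTH_COLUMNS))

    # add hom_ref reference records at FP sites (as a joint caller would)
    fp_sites = (pd.concat([c.df[c.df["pos"].isin(
        set(truth.loc[truth["event"] == "fp_injected", "pos"]))]
        [["chrom", "pos", "ref", "alt", "vtype"]] for c in cells])
        .drop_duplicates(subset=["chrom", "pos"])) if len(truth) else pd.DataFrame()
    if len(fp_sites):
        rng = _rng(config.seed, _STREAM_REF_FP_DEPTH)
        fp_sites = fp_sites.sort_values(["chrom", "pos"])
        ref_fp = fp_sites.assign(
            gt=HOM_REF,
            depth=np.maximum(rng.poisson(config.reference_depth_mean,
                                         size=len(fp_sites)), 6),
            mq=60,
        )
        merged = pd.concat([ref.df, ref_fp[REF_COLUMNS]], ignore_index=True)
        ref = PopulationReference(merged, sample_id=ref.sample_id)

    qc = None
    if qc_pass_probabilities is not None:
        qc = simulate_qc_matrix(config.n_cells, qc_pass_probabilities, config.seed)
    return SimulatedExperiment(config, target_region(config), ref, cells,
                               profiles, truth, qc)
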