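"""Coverage breadth, depth, uniformity (Lorenz curves) and target metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DepthProfile, TargetRegion


@dataclass
class LorenzCurve:
    """Cumulative (genome fraction, read fraction) pairs, depth-sorted.

    The diagonal is perfectly uniform coverage; any real curve lies on or
    below it. ``uniformity_index`` is a Gini-style summary: twice the area
    between the diagonal and the curve (0 = perfectly uniform).
    """

    points: np.ndarray  # (k, 2), starts at (0,0), ends at (1,1)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (k, 2) array")
        self.points = pts

    @property
    def uniformity_index(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        area_under = np.trapezoid(y, x)
        return float(2.0 * (0.5 - area_under))

    def interpolate(self, genome_fractions: np.ndarray) -> np.ndarray:
        """Cumulative read fraction at given genome fractions."""
        return np.interp(genome_fractions, self.points[:, 0], self.points[:, 1])


def _check_region(depth: DepthProfile, region: TargetRegion | None) -> TargetRegion:
    region = region or depth.region
    if region != depth.region:
        raise ValueError("depth profile does not cover the requested region")
    if region.total_bp == 0:
        raise ValueError("empty target region")
    return region


def coverage_breadth(depth: DepthProfile, region: TargetRegion | None = None,
                     min_depth: int = 1) -> float:
    """Fraction of target bases with depth >= ``min_depth``.

    With the default threshold this is coverage breadth (>=1X); with
    ``min_depth=6`` it is the callable fraction used by the variant-calling
    filters.
    """
    _check_region(depth, region)
    lengths = (depth.runs["end"] - depth.runs["start"]).to_numpy()
    hits = lengths[(depth.runs["depth"] >= min_depth).to_numpy()].sum()
    return float(hits) / float(lengths.sum())


def mean_depth(depth: DepthProfile, region: TargetRegion | None = None) -> float:
    """Arithmetic mean depth over all target bases (zeros included)."""
    _check_region(depth, region)
    lengths = (depth.runs["end"] - depth.runs["start"]).to_numpy()
    mass = (depth.runs["depth"].to_numpy() * lengths).sum()
    return float(mass) / float(lengths.sum())


def lorenz_curve(depth: DepthProfile, max_points: int = 10_000) -> LorenzCurve:
    """Lorenz curve of coverage uniformity.

    Bases are sorted by ascending depth; point k is
    (k / N, sum of the first k depths / total depth). The exact polyline is
    thinned to at most ``max_points`` points, always preserving endpoints
    and the run boundaries that define the curve's vertices.
    """
    runs = depth.runs
    lengths = (runs["end"] - runs["start"]).to_numpy(dtype=np.int64)
    values = runs["depth"].to_numpy(dtype=np.int64)
    # aggregate equal depths, then sort ascending: the curve only has a
    # vertex per distinct depth value
    order = np.argsort(values, kind="stable")
    values, lengths = values[order], lengths[order]
    uniq, start_idx = np.unique(values, return_index=True)
    counts = np.add.reduceat(lengths, start_idx)
    total_bases = counts.sum()
    total_reads = (uniq * counts).sum()
    if total_reads <= 0:
        raise ValueError("Lorenz curve undefined for an all-zero profile")
    cum_bases = np.cumsum(counts) / total_bases
    cum_reads = np.cumsum(uniq * counts) / total_reads
    x = np.concatenate(([0.0], cum_bases))
    y = np.concatenate(([0.0], cum_reads))
    if len(x) > max_points:
        idx = np.unique(np.round(np.linspace(0, len(x) - 1, max_points)).astype(int))
        x, y = x[idx], y[idx]
    x[-1], y[-1] = 1.0, 1.0
    return LorenzCurve(np.column_stack([x, y]))


def on_target_fraction(aligned_bases_in_region: float, total_aligned_bases: float
                       ) -> float:
    """Fraction of aligned sequence falling inside the capture target."""
    if total_aligned_bases <= 0:
        raise ValueError("total aligned bases must be positive")
    if aligned_bases_in_region < 0 or aligned_bases_in_region > total_aligned_bases:
        raise ValueError("in-region bases must lie in [0, total]")
    return float(aligned_bases_in_region) / float(total_aligned_bases)


def depth_histogram(depth: DepthProfile, region: TargetRegion | None = None,
                    max_bin: int = 100) -> np.ndarray:
    """Counts of target bases per depth value; depths above ``max_bin`` are
    pooled into the last bin. The histogram sums to the region size."""
    _check_region(depth, region)
    lengths = (depth.runs["end"] - depth.runs["start"]).to_numpy(dtype=np.int64)
    values = np.minimum(depth.runs["depth"].to_numpy(dtype=np.int64), max_bin)
    return np.bincount(values, weights=lengths, minlength=max_bin + 1).astype(np.int64)
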