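"""Simulation configuration for single-cell WGA exome call sets.

The generator emulates the error structure of MDA-amplified single-nucleus
exome data: a diploid population reference carrying het/hom SNVs and indels
over an exome-like target, per-cell over-dispersed coverage with uncovered
gaps, allelic dropout at heterozygous sites (with an allele bias and shared
recurrent hotspots), and rare transition-skewed false-positive het calls at
homozygous-reference sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 12 directional single-base substitution classes, lexicographic order.
SUBSTITUTION_CLASSES: tuple[str, ...] = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

#: The two classes produced by cytosine deamination during MDA, which
#: dominate the observed false-positive spectrum.
TRANSITION_CLASSES: tuple[str, str] = ("C>T", "G>A")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def default_fp_spectrum() -> np.ndarray:
    """Default FP substitution weights: 82.3% combined C>T + G>A mass,
    the remainder spread evenly over the other ten classes."""
    w = np.full(12, 0.177 / 10.0)
    for cls in TRANSITION_CLASSES:
        w[SUBSTITUTION_CLASSES.index(cls)] = 0.823 / 2.0
    return w / w.sum()


@dataclass
class SimulationConfig:
    """Parameters of one simulated single-cell exome experiment.

    Defaults emulate a G2/M-gated experiment on a normal diploid line:
    dropout 21.52% with a slight bias toward losing the reference allele,
    an SNV false-positive rate of 3.2e-5 per homozygous-reference base,
    ~96% coverage breadth, and variant densities scaled from a 62.3 Mb
    exome target down to a 1 Mb desk-scale target.

    Parameters
    ----------
    target_size_bp : int
        Size of the (single-contig) capture target in bases.
    n_cells : int
        Number of single cells.
    n_het_snvs, n_hom_snvs, n_het_indels, n_hom_indels : int
        Variant counts in the population reference.
    ado_rate : float
        Per-het-site, per-cell allelic dropout probability ``d``.
    ado_bb_bias : float
        Probability ``beta`` that a dropout at an AB site yields BB
        (loss of the reference allele) rather than AA.
    ado_hotspot_fraction : float
        Fraction of het sites whose dropout probability is elevated; the
        hotspot set is shared across cells, producing recurrent dropout.
    ado_hotspot_multiplier : float
        Dropout-rate multiplier at hotspots; the per-site probability is
        capped at 1.
    fp_rate : float
        Per-homozygous-reference-base probability of a spurious het call.
    fp_spectrum : ndarray
        Weights over :data:`SUBSTITUTION_CLASSES`; must sum to 1.
    depth_mean : float
        Mean per-base coverage of the non-zero component.
    depth_dispersion : float
        Negative-binomial over-dispersion ``alpha`` (variance =
        ``m + alpha * m**2``). Exactly 0 means deterministic constant depth.
    depth_zero_fraction : float
        Extra point mass at zero coverage (uncaptured/unamplified bases).
    mq_fail_rate, bq_fail_rate : float
        Per-record probabilities of failing the mapping-quality and
        base-quality criteria.
    reference_depth_mean : float
        Mean coverage of the population reference sample.
    chrom : str
        Contig name used for all simulated coordinates.
    seed : int
        Master seed; every stream of randomness derives from it.
    """

    target_size_bp: int = 1_000_000
    n_cells: int = 5
    n_het_snvs: int = 375
    n_hom_snvs: int = 187
    n_het_indels: int = 31
    n_hom_indels: int = 15
    ado_rate: float = 0.2152
    ado_bb_bias: float = 0.55
    ado_hotspot_fraction: float = 0.02
    ado_hotspot_multiplier: float = 3.0
    fp_rate: float = 3.2e-5
    fp_spectrum: np.ndarray = field(default_factory=default_fp_spectrum)
    depth_mean: float = 30.0
    depth_dispersion: float = 0.6
    depth_zero_fraction: float = 0.04
    mq_fail_rate: float = 0.002
    bq_fail_rate: float = 0.002
    reference_depth_mean: float = 59.0
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.fp_spectrum = np.asarray(self.fp_spectrum, dtype=float)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.target_size_bp < 1:
            raise ConfigurationError("target_size_bp must be >= 1")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        for name in ("n_het_snvs", "n_hom_snvs", "n_het_indels", "n_hom_indels"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_variants > self.target_size_bp:
            raise ConfigurationError(
                f"requested {self.n_variants} variant sites exceed the "
                f"{self.target_size_bp} bp target"
            )
        probs = {
            "ado_rate": self.ado_rate,
            "ado_bb_bias": self.ado_bb_bias,
            "ado_hotspot_fraction": self.ado_hotspot_fraction,
            "fp_rate": self.fp_rate,
            "depth_zero_fraction": self.depth_zero_fraction,
            "mq_fail_rate": self.mq_fail_rate,
            "bq_fail_rate": self.bq_fail_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if self.ado_hotspot_multiplier < 0:
            raise ConfigurationError("ado_hotspot_multiplier must be >= 0")
        if self.fp_spectrum.shape != (12,) or (self.fp_spectrum < 0).any():
            raise ConfigurationError("fp_spectrum must be 12 non-negative weights")
        if abs(float(self.fp_spectrum.sum()) - 1.0) > 1e-9:
            raise ConfigurationError("fp_spectrum must sum to 1 (tolerance 1e-9)")
        if self.depth_mean < 0 or self.depth_dispersion < 0:
            raise ConfigurationError("depth_mean and depth_dispersion must be >= 0")

    # -- derived quantities ---------------------------------------------

    @property
    def n_variants(self) -> int:
        return self.n_het_snvs + self.n_hom_snvs + self.n_het_indels + self.n_hom_indels

    @property
    def hotspot_ado_rate(self) -> float:
        """Dropout probability at a hotspot het site, capped at 1."""
        return min(1.0, self.ado_rate * self.ado_hotspot_multiplier)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["fp_spectrum"] = [float(x) for x in self.fp_spectrum]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)
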