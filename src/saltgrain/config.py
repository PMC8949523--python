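"""Configuration objects for simulation and association scanning.

All positions are 1-based base pairs (VCF convention). Genotypes are coded
as 0/1/2 dosage of the coded (minor at simulation time) allele; missing
calls are encoded distinctly (-1), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when a simulation or scan configuration is inconsistent."""


SUBPOP_NAMES = ("Oil", "OF", "Fiber")

#: trait families measured at germination: relative germination rate,
#: relative shoot length, relative root length
TRAIT_FAMILIES = ("RGR", "RSL", "RRL")


@dataclass(frozen=True)
class PlantedQTL:
    """A causal locus planted in the synthetic panel.

    Parameters
    ----------
    chrom, pos
        1-based location; ``pos`` must fall inside the chromosome.
    effect_size
        Additive effect per copy of the favorable allele, on the scale of
        the relative trait (a dimensionless ratio).
    affected_traits
        Subset of ``("RGR", "RSL", "RRL")`` the locus acts on.
    favored_subpop
        Optional subpopulation whose favorable-allele frequency is elevated,
        emulating subpopulation-biased tolerance alleles.
    """

    chrom: str
    pos: int
    effect_size: float
    affected_traits: tuple[str, ...] = TRAIT_FAMILIES
    favored_subpop: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ConfigurationError(f"QTL position must be >=1, got {self.pos}")
        import math

        if not math.isfinite(self.effect_size):
            raise ConfigurationError("QTL effect_size must be finite")
        bad = set(self.affected_traits) - set(TRAIT_FAMILIES)
        if bad or not self.affected_traits:
            raise ConfigurationError(f"affected_traits must be a non-empty subset of {TRAIT_FAMILIES}, got {self.affected_traits}")


@dataclass
class SimConfig:
    """Conditions for the synthetic diversity panel.

    Defaults emulate a germination-stage salt-tolerance study design at desk
    scale: 200 accessions in three subpopulations (oil, oil-fiber
    intermediate, fiber), 15 chromosomes, biallelic SNPs with MAF >= 0.05,
    LD decaying to r^2 ~ 0.1 at 54 kb, and three correlated environments.
    """

    n_accessions: int = 200
    subpop_props: tuple[float, float, float] = (0.50, 0.20, 0.30)
    subpop_names: tuple[str, ...] = SUBPOP_NAMES
    fst: float = 0.10
    n_chrom: int = 15
    snps_per_chrom: int = 200
    chrom_length_bp: int = 20_000_000
    ld_decay_bp: int = 54_000
    maf_min: float = 0.05
    missing_rate: float = 0.05
    n_envs: int = 3
    planted_qtls: list[PlantedQTL] = field(default_factory=list)
    h2: float = 0.5
    env_corr: float = 0.7
    trait_corr: float = 0.88  # within-environment cross-trait correlation target
    n_seeds_germ: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subpop_props) - 1.0) > 1e-9:
            raise ConfigurationError("subpop_props must sum to 1")
        if len(self.subpop_props) != len(self.subpop_names):
            raise ConfigurationError("subpop_props and subpop_names length mismatch")
        if not (0.0 <= self.missing_rate < 0.2):
            raise ConfigurationError("missing_rate must be in [0, 0.2)")
        if not (0.0 < self.maf_min <= 0.5):
            raise ConfigurationError("maf_min must be in (0, 0.5]")
        if not (0.0 <= self.h2 <= 1.0):
            raise ConfigurationError("h2 must be in [0, 1]")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigurationError("fst must be in [0, 1)")
        if self.snps_per_chrom > self.chrom_length_bp:
            raise ConfigurationError("snps_per_chrom exceeds chromosome length: no room for distinct positions")
        if self.n_envs < 1:
            raise ConfigurationError("n_envs must be >= 1")
        for q in self.planted_qtls:
            if q.pos > self.chrom_length_bp:
                raise ConfigurationError(f"QTL at {q.chrom}:{q.pos} lies beyond chrom_length_bp={self.chrom_length_bp}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i}" for i in range(1, self.n_chrom + 1)]


def demo_planted_qtls() -> list[PlantedQTL]:
    """Three multi-trait tolerance loci with oil-subpopulation-biased
    favorable alleles, echoing repeatedly detected loci on chromosomes
    2, 4 and 10."""
    return [
        PlantedQTL("Chr2", 17_310_510, 0.12, ("RGR", "RSL", "RRL"), favored_subpop="Oil"),
        PlantedQTL("Chr4", 5_400_000, 0.10, ("RGR", "RSL"), favored_subpop="Oil"),
        PlantedQTL("Chr10", 12_000_000, 0.10, ("RSL", "RRL"), favored_subpop="Oil"),
    ]


@dataclass
class ScanConfig:
    """Filters, covariates and thresholds for the association scan.

    ``mlm_threshold_log10p`` is a fixed significance cut on the -log10(p)
    scale for the mixed model; the general-linear-model threshold is derived
    by Bonferroni correction from the realized post-filter test count.
    """

    maf_min: float = 0.05
    missing_max: float = 0.2
    n_pcs: int = 3
    alpha: float = 0.05
    mlm_threshold_log10p: float = 5.00
    models: tuple[str, ...] = ("GLM", "MLM")

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_pcs < 0:
            raise ConfigurationError("n_pcs must be >= 0")
        if not self.models:
            raise ConfigurationError("models must be non-empty")
        bad = set(m.upper() for m in self.models) - {"GLM", "MLM"}
        if bad:
            raise ConfigurationError(f"unknown models: {sorted(bad)}")
        self.models = tuple(m.upper() for m in self.models)
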