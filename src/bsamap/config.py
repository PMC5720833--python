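"""Simulation configuration for the in-silico interspecies cross.

The defaults describe the cross that is being emulated: two collinear
7-chromosome yeast genomes at ~10% nucleotide divergence, a single-base
causal insertion in one parent's copy of a target gene, haploid meiotic
segregants pooled by phenotype and mating type into pools of
30/35/35/52 clones, and 51-bp unpaired error-bearing reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple


class ConfigError(ValueError):
    """Raised when a simulation configuration cannot produce a valid genome."""


#: Pool order: (phenotype, mating_type, library name). Matches the pool-size
#: order 30/35/35/52 = alpha switchers, alpha non-switchers, a switchers,
#: a non-switchers.
POOL_SPECS = (
    ("switcher", "alpha", "SW_alpha"),
    ("non_switcher", "alpha", "NS_alpha"),
    ("switcher", "a", "SW_a"),
    ("non_switcher", "a", "NS_a"),
)

LIBRARIES = tuple(spec[2] for spec in POOL_SPECS) + ("parent_A", "parent_B")

_GENE_ID_RE = re.compile(r"^c(\d+)g(\d+)$")


def parse_gene_id(gene_id: str) -> Tuple[int, int]:
    """Split a simulator gene id 'c<chrom>g<index>' into 1-based ints."""
    m = _GENE_ID_RE.match(gene_id)
    if not m:
        raise ConfigError(f"malformed gene id {gene_id!r}; expected c<chrom>g<index>")
    return int(m.group(1)), int(m.group(2))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cross. The seed fully determines every output."""

    n_chromosomes: int = 7
    genes_per_chromosome: int = 10
    gene_length_range: Tuple[int, int] = (900, 1500)       # nt, rounded down to codons
    intergenic_length_range: Tuple[int, int] = (300, 800)  # nt
    divergence_rate: float = 0.10          # substitutions per site, genic + intergenic
    micro_indel_rate: float = 0.01         # 1-bp indels per site, intergenic only
    causal_gene: Optional[str] = "c6g05"
    causal_cds_length: int = 1314          # intact allele encodes 437 residues
    causal_insertion_offset: int = 512     # 1-based CDS coordinate of the extra base
    n_segregants: int = 400                # screened clones; pools draw 152 of them
    crossovers_per_chromosome: float = 2.0
    penetrance: float = 1.0
    misclassification_rate: float = 0.0
    pool_sizes: Tuple[int, int, int, int] = (30, 35, 35, 52)
    read_length: int = 51
    per_clone_coverage: float = 0.5        # fold coverage contributed by each clone
    parent_coverage: float = 20.0          # fold coverage of each parental library
    sequencing_error_rate: float = 0.002   # per-base substitution errors
    clone_weight_dispersion: float = 0.0   # optional unequal-pooling knob (gamma CV^2)
    incompatibility_pair: Optional[Tuple[str, str]] = None
    mating_type_locus: str = "c3g05"
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "divergence_rate": self.divergence_rate,
            "micro_indel_rate": self.micro_indel_rate,
            "penetrance": self.penetrance,
            "misclassification_rate": self.misclassification_rate,
            "sequencing_error_rate": self.sequencing_error_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ConfigError("need at least one chromosome and one gene per chromosome")
        lo, hi = self.gene_length_range
        if not (9 <= lo <= hi):
            raise ConfigError(f"gene_length_range {self.gene_length_range} cannot hold an ORF")
        ilo, ihi = self.intergenic_length_range
        if not (0 <= ilo <= ihi):
            raise ConfigError(f"invalid intergenic_length_range {self.intergenic_length_range}")
        if len(self.pool_sizes) != 4 or any(s < 0 for s in self.pool_sizes):
            raise ConfigError("pool_sizes must be four non-negative counts")
        if sum(self.pool_sizes) > self.n_segregants:
            raise ConfigError(
                f"pool sizes sum to {sum(self.pool_sizes)} but only "
                f"{self.n_segregants} segregants are simulated"
            )
        if self.read_length < 1:
            raise ConfigError("read_length must be positive")
        if self.per_clone_coverage <= 0 or self.parent_coverage <= 0:
            raise ConfigError("coverage must be positive")
        if self.crossovers_per_chromosome < 0:
            raise ConfigError("crossovers_per_chromosome must be non-negative")
        if self.causal_cds_length % 3 or self.causal_cds_length < 9:
            raise ConfigError("causal_cds_length must be a positive multiple of 3")
        for gid in filter(None, [self.causal_gene, self.mating_type_locus,
                                 *(self.incompatibility_pair or ())]):
            chrom, idx = parse_gene_id(gid)
            if not (1 <= chrom <= self.n_chromosomes and 1 <= idx <= self.genes_per_chromosome):
                raise ConfigError(
                    f"gene {gid} outside the simulated layout "
                    f"({self.n_chromosomes} chromosomes x {self.genes_per_chromosome} genes)"
                )
        if self.causal_gene is not None and not (1 <= self.causal_insertion_offset <= self.causal_cds_length):
            raise ConfigError("causal_insertion_offset must fall inside the causal CDS")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["intergenic_length_range"] = list(self.intergenic_length_range)
        d["pool_sizes"] = list(self.pool_sizes)
        if self.incompatibility_pair is not None:
            d["incompatibility_pair"] = list(self.incompatibility_pair)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for key in ("gene_length_range", "intergenic_length_range", "pool_sizes",
                    "incompatibility_pair"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
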