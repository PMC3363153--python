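"""Simulation configuration.

The default configuration emulates the shape of a simulated
genomic-selection workshop cohort: 3000 individuals in a 3-generation
pedigree descending from 200
founders, five chromosomes of 1998 SNPs each, 2000 individuals with known
phenotypes and 1000 masked for validation, and planted groups of markers in
complete mutual LD so the r^2 = 1 selection stage has exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Planted perfect-LD groups per chromosome as (block_size, n_blocks) pairs.
#: Sizes 2..8 mirror the subset-length range seen in dense SNP panels after
#: complete-LD grouping; 2-SNP groups dominate.
DEFAULT_LD_BLOCKS: tuple[tuple[int, int], ...] = ((2, 60), (3, 12), (4, 3), (5, 1), (8, 1))

# Stage names -> fixed spawn index of the per-stage RNG stream.
_STAGE_STREAMS = {
    "pedigree": 0,
    "layout": 1,
    "founders": 2,
    "meiosis": 3,
    "qtl": 4,
    "phenotype": 5,
}


@dataclass(kw_only=True)
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    Attributes
    ----------
    n_founders
        Size of the unrelated base generation. Founders are pair-mated
        monogamously, so the count must be even.
    n_generations
        Number of offspring generations bred after the founders.
    offspring_per_mating
        Full-sib family size for every mating pair.
    n_chromosomes, markers_per_chromosome
        Genome shape; defaults follow the 5 x 1998 SNP panel layout.
    ld_block_spec
        Per-chromosome planted perfect-LD groups, ``(block_size, n_blocks)``.
        Each group is one freely segregating source marker plus exact copy or
        complement columns, so pairwise dosage r^2 is exactly 1 within it.
    n_qtl
        Number of additive QTL, drawn uniformly over all markers with
        standard-normal effect sizes.
    heritability
        Narrow-sense h^2 of the single trait; fixes the residual variance
        relative to the realised breeding-value variance.
    n_known_phenotypes
        Individuals (in pedigree order, oldest first) whose phenotype is
        observed; the remainder form the masked validation set.
    expected_crossovers
        Mean number of crossovers per chromosome per meiosis (Poisson).
    residual_variance_fallback
        Residual variance used when h^2 = 0 leaves it undetermined.
    seed
        Root seed; every stochastic stage consumes an independent stream
        derived from it, keyed by stage name.
    """

    seed: int
    n_founders: int = 200
    n_generations: int = 3
    offspring_per_mating: int = 4
    n_chromosomes: int = 5
    markers_per_chromosome: int = 1998
    ld_block_spec: tuple[tuple[int, int], ...] = field(default=DEFAULT_LD_BLOCKS)
    n_qtl: int = 100
    heritability: float = 0.3
    n_known_phenotypes: int = 2000
    expected_crossovers: float = 1.0
    residual_variance_fallback: float = 1.0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("need at least 2 founders")
        if self.n_founders % 2:
            raise ConfigurationError(
                f"monogamous pair mating needs an even founder count, got {self.n_founders}"
            )
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if not 0.0 <= self.heritability <= 1.0:
            raise ConfigurationError(f"heritability must lie in [0, 1], got {self.heritability}")
        self.ld_block_spec = tuple((int(a), int(b)) for a, b in self.ld_block_spec)
        block_markers = sum(size * count for size, count in self.ld_block_spec)
        largest = max((size for size, _ in self.ld_block_spec), default=0)
        if largest > self.markers_per_chromosome or block_markers > self.markers_per_chromosome:
            raise ConfigurationError(
                "planted LD blocks do not fit on a chromosome of "
                f"{self.markers_per_chromosome} markers"
            )
        if any(size < 2 or count < 0 for size, count in self.ld_block_spec):
            raise ConfigurationError("ld_block_spec entries must be (size >= 2, count >= 0)")
        if self.expected_crossovers < 0:
            raise ConfigurationError("expected_crossovers must be >= 0")
        if self.n_known_phenotypes > self.total_individuals:
            raise ConfigurationError(
                f"n_known_phenotypes={self.n_known_phenotypes} exceeds the "
                f"{self.total_individuals} individuals this pedigree produces"
            )

    @property
    def generation_sizes(self) -> list[int]:
        """Cohort sizes, founders first."""
        sizes = [self.n_founders]
        for _ in range(self.n_generations):
            n_pairs = sizes[-1] // 2
            sizes.append(n_pairs * self.offspring_per_mating)
        return sizes

    @property
    def total_individuals(self) -> int:
        return sum(self.generation_sizes)

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def stream(self, stage: str) -> np.random.Generator:
        """Independent RNG stream for a named stage, derived from the root seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGE_STREAMS))
        return np.random.default_rng(children[_STAGE_STREAMS[stage]])
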