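"""In-memory containers shared across the pipeline.

Conventions: individual ids are positive integers with 0 meaning "unknown
parent"; marker map positions are 0-based base pairs in memory (1-based in
files); genotype dosages count copies of the designated counted allele and
lie in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PedigreeError, ValidationError


@dataclass
class Pedigree:
    """Three-column pedigree (individual, sire, dam), 0 = unknown parent.

    Records are expected in topological order: every parent appears as an
    individual on an earlier row (or is unknown). ``validate`` enforces this,
    which also rules out ancestry cycles.
    """

    ids: np.ndarray
    sires: np.ndarray
    dams: np.ndarray
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sires = np.asarray(self.sires, dtype=np.int64)
        self.dams = np.asarray(self.dams, dtype=np.int64)
        if not (self.ids.shape == self.sires.shape == self.dams.shape):
            raise PedigreeError("id, sire and dam columns differ in length")

    def __len__(self) -> int:
        return self.ids.size

    @property
    def index(self) -> dict[int, int]:
        return {int(i): k for k, i in enumerate(self.ids)}

    def validate(self) -> None:
        if self.ids.size != np.unique(self.ids).size:
            dupes = pd.Series(self.ids)
            dupes = dupes[dupes.duplicated()].tolist()
            raise PedigreeError(f"duplicated individual ids: {dupes[:5]}")
        if np.any(self.ids <= 0):
            raise PedigreeError("individual ids must be positive (0 is reserved for unknown)")
        seen: set[int] = set()
        for i, s, d in zip(self.ids, self.sires, self.dams):
            for p in (s, d):
                if p != 0 and int(p) not in seen:
                    msg = (
                        f"parent {p} of individual {i} does not precede it "
                        "(missing, out of order, or part of a cycle)"
                    )
                    raise PedigreeError(msg)
            seen.add(int(i))

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of each individual's sire and dam; -1 for unknown."""
        idx = self.index
        s = np.array([idx.get(int(p), -1) if p else -1 for p in self.sires], dtype=np.int64)
        d = np.array([idx.get(int(p), -1) if p else -1 for p in self.dams], dtype=np.int64)
        return s, d


@dataclass
class GenotypeDataset:
    """Dosage matrix with marker map, pedigree and (optionally) phenotypes.

    ``marker_map`` columns: chrom (str), marker (str), pos (int, 0-based).
    ``phenotypes`` is NaN where unobserved; ``known_mask`` marks the training
    individuals.
    """

    ids: np.ndarray
    marker_map: pd.DataFrame
    dosages: np.ndarray
    pedigree: Pedigree
    phenotypes: np.ndarray | None = None
    known_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.dosages = np.asarray(self.dosages)

    @property
    def n_individuals(self) -> int:
        return self.ids.size

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != self.ids.size:
            raise ValidationError(
                f"dosage matrix has {n} rows but {self.ids.size} individual ids"
            )
        if m != len(self.marker_map):
            raise ValidationError(
                f"dosage matrix has {m} columns but the map lists {len(self.marker_map)} markers"
            )
        if self.ids.size != np.unique(self.ids).size:
            raise ValidationError("duplicated individual ids in genotype data")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} outside {{0,1,2}} for individual "
                f"{self.ids[i]} at marker {self.marker_map['marker'].iloc[j]}"
            )
        self.pedigree.validate()
        missing = set(self.ids.tolist()) - set(self.pedigree.ids.tolist())
        if missing:
            raise ValidationError(
                f"genotyped individuals absent from the pedigree: {sorted(missing)[:5]}"
            )
        if self.phenotypes is not None:
            if self.phenotypes.shape != (n,):
                raise ValidationError("phenotype vector length mismatch")
            if self.known_mask is None:
                raise ValidationError("phenotypes present but known_mask missing")
            if self.known_mask.shape != (n,):
                raise ValidationError("known_mask length mismatch")
            if np.isnan(self.phenotypes[self.known_mask]).any():
                raise ValidationError("NaN phenotype flagged as known")


@dataclass
class TruthBundle:
    """Generator ground truth: phase, QTL architecture and true breeding values.

    ``haplotypes`` has shape (n_individuals, 2, n_markers) over all
    chromosomes in map order; slot 0 is the paternal, slot 1 the maternal
    haplotype.
    """

    haplotypes: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    ld_blocks: list["LDSubset"] = field(default_factory=list)


@dataclass
class LDSubset:
    """Ordered group of markers on one chromosome in complete mutual LD."""

    chrom: str
    members: np.ndarray  # marker column indices, ordered by map position

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)

    @property
    def size(self) -> int:
        return self.members.size


@dataclass
class SubsetCatalog:
    """Haplotype catalog for one LD subset.

    ``haplotypes`` is (H, L) over {0, 1}; ``frequencies`` the EM estimates
    (summing to 1 before filtering); ``retained`` the >= threshold flags.
    """

    subset: LDSubset
    haplotypes: np.ndarray
    frequencies: np.ndarray
    retained: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.frequencies)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def labels(self) -> list[str]:
        return ["".join(map(str, row)) for row in self.haplotypes]


@dataclass
class DiplotypeAssignment:
    """Most-probable haplotype pair per individual for one subset."""

    pairs: np.ndarray  # (n, 2) catalog indices, pairs[:, 0] <= pairs[:, 1]
    posterior: np.ndarray  # (n,)
    flagged: np.ndarray  # True where no nonzero-frequency pair existed


@dataclass
class HaplotypeDesign:
    """Individuals x retained-haplotypes copy-count matrix.

    Column metadata records, for each retained haplotype, its subset id, the
    subset length L (number of SNPs) and the subset's retained-haplotype
    count m — the quantities entering the heterogeneous-variance model.
    """

    row_ids: np.ndarray
    matrix: np.ndarray
    col_subset: np.ndarray
    col_hap: np.ndarray
    col_label: list[str]
    col_length: np.ndarray
    col_n_retained: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class VarianceComponents:
    """Genetic and residual variances with optional per-column scales."""

    sigma2_g: float
    sigma2_e: float
    method: str = "spectral-reml"
    converged: bool = True

    @property
    def ratio(self) -> float:
        """lambda = sigma2_e / sigma2_g, the shrinkage parameter of the MME."""
        return self.sigma2_e / self.sigma2_g


@dataclass
class ModelFit:
    """Result of one fitted model.

    ``breeding_values`` and ``predicted_phenotypes`` (= mu + breeding value)
    cover every individual, phenotyped or not. ``effects`` are haplotype
    effects for the marker models and polygenic effects for the animal model.
    """

    model: str
    mu: float
    effects: np.ndarray
    variance_components: VarianceComponents | None
    breeding_values: np.ndarray
    predicted_phenotypes: np.ndarray
    individual_ids: np.ndarray
    extra: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    """Pearson correlation with Fisher-z confidence interval."""

    label: str
    r: float
    n: int
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def __str__(self) -> str:
        return f"{self.r:.4f}({self.ci_low:.4f}, {self.ci_high:.4f})"
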