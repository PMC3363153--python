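"""Synthetic dataset generator with known ground truth.

Founder haplotypes are drawn marker-by-marker from allele frequencies
uniform on (0.01, 0.5) — placing markers on both sides of the 5% MAF
threshold — and dropped through a multi-generation monogamous pedigree
with Poisson-distributed crossovers. Groups of markers in exact complete
LD are planted as copy/complement columns of a freely segregating source
marker, so the r^2 = 1 grouping stage has exact, tolerance-free truth.
A single additive trait is simulated from uniformly placed QTL with
standard-normal effects and Gaussian residuals scaled to the requested
heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .datatypes import GenotypeDataset, LDSubset, Pedigree, TruthBundle
from .errors import ConfigurationError

_BP_PER_MARKER = 1000  # uniform marker spacing on the synthetic map


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Breed a multi-generation pedigree by monogamous pair mating.

    Founders (generation 0) have unknown parents (code 0). In each later
    generation the previous cohort is randomly paired; every pair produces
    ``offspring_per_mating`` full sibs. Individuals are numbered 1..N in
    topological order, so parents always precede offspring.
    """
    rng = config.stream("pedigree")
    ids: list[int] = list(range(1, config.n_founders + 1))
    sires = [0] * config.n_founders
    dams = [0] * config.n_founders
    gens = [0] * config.n_founders

    previous = np.array(ids)
    next_id = config.n_founders + 1
    for g in range(1, config.n_generations + 1):
        if previous.size < 2:
            raise ConfigurationError(f"generation {g - 1} too small to mate ({previous.size})")
        shuffled = rng.permutation(previous)
        n_pairs = shuffled.size // 2
        cohort = []
        for p in range(n_pairs):
            sire, dam = int(shuffled[2 * p]), int(shuffled[2 * p + 1])
            for _ in range(config.offspring_per_mating):
                ids.append(next_id)
                sires.append(sire)
                dams.append(dam)
                gens.append(g)
                cohort.append(next_id)
                next_id += 1
        previous = np.array(cohort)

    ped = Pedigree(
        ids=np.array(ids),
        sires=np.array(sires),
        dams=np.array(dams),
        generation=np.array(gens),
    )
    ped.validate()
    return ped


@dataclass
class _ChromosomeLayout:
    """Where the planted perfect-LD blocks sit on one chromosome."""

    core_cols: np.ndarray  # columns simulated freely (incl. block sources)
    source_of: np.ndarray  # per column: source column index, or -1 if core
    flip: np.ndarray  # per column: True if the copy is the complement
    blocks: list[np.ndarray]  # member columns of each planted block, ordered


def _layout_chromosome(config: SimulationConfig, rng: np.random.Generator) -> _ChromosomeLayout:
    m = config.markers_per_chromosome
    source_of = np.full(m, -1, dtype=np.int64)
    flip = np.zeros(m, dtype=bool)
    blocks: list[np.ndarray] = []
    occupied = np.zeros(m, dtype=bool)

    specs = [size for size, count in config.ld_block_spec for _ in range(count)]
    for size in sorted(specs, reverse=True):  # place large blocks first
        for _ in range(10_000):
            start = int(rng.integers(0, m - size + 1))
            if not occupied[start : start + size].any():
                break
        else:  # pragma: no cover - only dense packings
            raise ConfigurationError("could not place planted LD blocks without overlap")
        cols = np.arange(start, start + size)
        occupied[cols] = True
        source = cols[0]
        for c in cols[1:]:
            source_of[c] = source
            flip[c] = bool(rng.integers(2))
        blocks.append(cols)

    core_cols = np.flatnonzero(source_of < 0)
    return _ChromosomeLayout(core_cols=core_cols, source_of=source_of, flip=flip, blocks=blocks)


def _meiosis(
    parent_haps: np.ndarray,
    pos_bp: np.ndarray,
    chrom_len: float,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a parent's two haplotypes with Poisson crossovers."""
    start = int(rng.integers(2))
    k = int(rng.poisson(rate))
    if k == 0:
        return parent_haps[start].copy()
    crossovers = np.sort(rng.uniform(0.0, chrom_len, size=k))
    segment = np.searchsorted(crossovers, pos_bp, side="right")
    phase = (start + segment) % 2
    return np.where(phase == 0, parent_haps[0], parent_haps[1])


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[GenotypeDataset, TruthBundle]:
    """Gene-drop founder haplotypes and assemble the genotype dataset.

    Returns the dataset (phenotypes not yet filled) and a truth bundle with
    the full phase, the QTL architecture and true breeding values.
    """
    n = len(pedigree)
    m_chrom = config.markers_per_chromosome
    m_total = config.n_markers
    layout_rng = config.stream("layout")
    founder_rng = config.stream("founders")
    meiosis_rng = config.stream("meiosis")

    sire_idx, dam_idx = pedigree.parent_indices()
    haplotypes = np.zeros((n, 2, m_total), dtype=np.int8)
    chrom_labels: list[str] = []
    marker_names: list[str] = []
    positions: list[int] = []
    planted_blocks: list[LDSubset] = []

    for c in range(config.n_chromosomes):
        layout = _layout_chromosome(config, layout_rng)
        col0 = c * m_chrom
        pos_bp = np.arange(m_chrom, dtype=np.float64) * _BP_PER_MARKER
        chrom_len = float(m_chrom * _BP_PER_MARKER)

        core = layout.core_cols
        freqs = founder_rng.uniform(0.01, 0.5, size=core.size)
        founder_haps = (
            founder_rng.random((2 * config.n_founders, core.size)) < freqs
        ).astype(np.int8)

        chrom_haps = np.zeros((n, 2, core.size), dtype=np.int8)
        core_pos = pos_bp[core]
        for i in range(n):
            si, di = sire_idx[i], dam_idx[i]
            if si < 0 and di < 0:  # founder
                chrom_haps[i, 0] = founder_haps[2 * i]
                chrom_haps[i, 1] = founder_haps[2 * i + 1]
            else:
                chrom_haps[i, 0] = _meiosis(
                    chrom_haps[si], core_pos, chrom_len, config.expected_crossovers, meiosis_rng
                )
                chrom_haps[i, 1] = _meiosis(
                    chrom_haps[di], core_pos, chrom_len, config.expected_crossovers, meiosis_rng
                )

        # scatter core columns, then materialise the planted copies
        haplotypes[:, :, col0 + core] = chrom_haps
        copy_cols = np.flatnonzero(layout.source_of >= 0)
        for j in copy_cols:
            src = layout.source_of[j]
            copied = haplotypes[:, :, col0 + src]
            haplotypes[:, :, col0 + j] = (1 - copied) if layout.flip[j] else copied

        planted_blocks.extend(
            LDSubset(chrom=str(c + 1), members=col0 + block) for block in layout.blocks
        )
        chrom_labels.extend([str(c + 1)] * m_chrom)
        marker_names.extend(f"c{c + 1}m{j + 1}" for j in range(m_chrom))
        positions.extend(int(p) for p in pos_bp)

    qtl_rng = config.stream("qtl")
    qtl_indices = np.sort(qtl_rng.choice(m_total, size=min(config.n_qtl, m_total), replace=False))
    qtl_effects = qtl_rng.standard_normal(qtl_indices.size)

    dosages = haplotypes.sum(axis=1, dtype=np.int8)
    true_bv = dosages[:, qtl_indices].astype(np.float64) @ qtl_effects

    marker_map = pd.DataFrame(
        {"chrom": chrom_labels, "marker": marker_names, "pos": positions}
    )
    dataset = GenotypeDataset(
        ids=pedigree.ids.copy(), marker_map=marker_map, dosages=dosages, pedigree=pedigree
    )
    truth = TruthBundle(
        haplotypes=haplotypes,
        qtl_indices=qtl_indices,
        qtl_effects=qtl_effects,
        true_breeding_values=true_bv,
        ld_blocks=planted_blocks,
    )
    return dataset, truth


def simulate_phenotypes(
    dataset: GenotypeDataset, truth: TruthBundle, config: SimulationConfig
) -> GenotypeDataset:
    """Fill phenotypes at the configured heritability and mask the validation set.

    Residual variance is Var(BV) * (1 - h^2) / h^2, using the empirical
    variance of the simulated breeding values, so the realised h^2 matches
    the request on average. h^2 = 1 gives phenotype == breeding value;
    h^2 = 0 gives pure noise at the configured fallback variance (the trait
    then carries no heritable signal at all).
    """
    rng = config.stream("phenotype")
    h2 = config.heritability
    bv = truth.true_breeding_values
    var_bv = float(np.var(bv))

    genetic = bv
    if h2 == 0.0 or var_bv == 0.0:
        if var_bv > 0.0:
            warnings.warn(
                "heritability 0 with nonzero QTL effects: phenotypes are pure "
                "noise at the fallback residual variance",
                stacklevel=2,
            )
        genetic = np.zeros_like(bv)
        resid_var = config.residual_variance_fallback
    elif h2 == 1.0:
        resid_var = 0.0
    else:
        resid_var = var_bv * (1.0 - h2) / h2

    noise = rng.normal(0.0, np.sqrt(resid_var), size=bv.size) if resid_var > 0 else 0.0
    phenotypes = genetic + noise

    known = np.zeros(bv.size, dtype=bool)
    known[: config.n_known_phenotypes] = True  # oldest individuals first

    dataset.phenotypes = phenotypes
    dataset.known_mask = known
    return dataset


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeDataset, TruthBundle]:
    """Pedigree + genotypes + phenotypes in one call."""
    pedigree = simulate_pedigree(config)
    dataset, truth = simulate_genotypes(pedigree, config)
    simulate_phenotypes(dataset, truth, config)
    return dataset, truth
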