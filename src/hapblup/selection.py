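"""Marker selection: MAF filtering and grouping of markers in complete LD.

LD is measured as the squared Pearson correlation of genotype dosages
(composite LD). For the r^2 = 1 decision this coincides with the
haplotype-level definition whenever one marker is a deterministic copy or
complement of another, and it requires no phase information. Markers in
complete LD with at least one other marker on the same chromosome are
grouped into subsets (connected components of the r^2 >= 1 - tol graph);
|r| = 1 is transitive, so in exact arithmetic each component is a clique.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, LDSubset
from .errors import ValidationError

DEFAULT_MAF_THRESHOLD = 0.05
DEFAULT_R2_TOLERANCE = 1e-9


def compute_maf(dataset: GenotypeDataset, individuals: np.ndarray | None = None) -> pd.DataFrame:
    """Per-marker counted-allele frequency and minor allele frequency.

    frequency = (sum of dosages) / (2 * n individuals); maf = min(f, 1 - f).
    ``individuals`` optionally restricts to a boolean mask of rows (e.g. the
    phenotyped subset); default is all genotyped individuals.

    Returns a DataFrame with columns marker, chrom, freq, maf.
    """
    dosages = dataset.dosages if individuals is None else dataset.dosages[individuals]
    n = dosages.shape[0]
    if n == 0:
        raise ValidationError("cannot compute allele frequencies over zero individuals")
    freq = dosages.sum(axis=0, dtype=np.float64) / (2.0 * n)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {
            "marker": dataset.marker_map["marker"].to_numpy(),
            "chrom": dataset.marker_map["chrom"].to_numpy(),
            "freq": freq,
            "maf": maf,
        }
    )


def filter_by_maf(maf_records: pd.DataFrame, threshold: float = DEFAULT_MAF_THRESHOLD) -> np.ndarray:
    """Column indices of markers retained at the MAF threshold, in map order.

    Markers with MAF *lower than* the threshold are excluded, so equality is
    retained.
    """
    if not 0.0 < threshold < 0.5:
        raise ValidationError(f"MAF threshold must lie in (0, 0.5), got {threshold}")
    return np.flatnonzero(maf_records["maf"].to_numpy() >= threshold)


def pairwise_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD)."""
    a = np.asarray(dosage_a, dtype=np.float64)
    b = np.asarray(dosage_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("r^2 needs two equal-length vectors with >= 2 entries")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("r^2 undefined for a constant (monomorphic) dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def group_perfect_ld(
    dataset: GenotypeDataset,
    retained: np.ndarray,
    tolerance: float = DEFAULT_R2_TOLERANCE,
) -> list[LDSubset]:
    """Group retained markers of each chromosome into complete-LD subsets.

    Builds, per chromosome, a graph over the retained markers with an edge
    wherever r^2 >= 1 - tolerance, and returns its connected components of
    size >= 2 as :class:`LDSubset` objects with members ordered by map
    position. Singletons (markers in complete LD with no other marker) are
    discarded. Subsets are returned in (chromosome, first-member-position)
    order.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    retained = np.asarray(retained, dtype=np.int64)
    chroms = dataset.marker_map["chrom"].to_numpy()
    positions = dataset.marker_map["pos"].to_numpy()

    subsets: list[LDSubset] = []
    for chrom in pd.unique(chroms):
        cols = retained[chroms[retained] == chrom]
        if cols.size < 2:
            continue
        block = dataset.dosages[:, cols].astype(np.float64)
        sd = block.std(axis=0)
        ok = sd > 0  # monomorphic columns cannot participate
        cols = cols[ok]
        if cols.size < 2:
            continue
        corr = np.corrcoef(block[:, ok], rowvar=False)
        r2 = corr * corr
        np.fill_diagonal(r2, 0.0)
        ii, jj = np.nonzero(np.triu(r2 >= 1.0 - tolerance, k=1))

        graph = nx.Graph()
        graph.add_nodes_from(range(cols.size))
        graph.add_edges_from(zip(ii.tolist(), jj.tolist()))
        for component in nx.connected_components(graph):
            if len(component) < 2:
                continue
            members = cols[sorted(component)]
            members = members[np.argsort(positions[members], kind="stable")]
            subsets.append(LDSubset(chrom=str(chrom), members=members))

    subsets.sort(key=lambda s: (s.chrom, int(positions[s.members[0]])))
    return subsets


def subset_size_histogram(subsets: list[LDSubset]) -> pd.DataFrame:
    """Per-chromosome counts of subsets by size (the Table-2-style report)."""
    rows = [{"chrom": s.chrom, "size": s.size} for s in subsets]
    if not rows:
        return pd.DataFrame(columns=["chrom", "size", "count"])
    df = pd.DataFrame(rows)
    out = df.value_counts(["chrom", "size"]).reset_index(name="count")
    return out.sort_values(["chrom", "size"]).reset_index(drop=True)


def participating_markers(subsets: list[LDSubset]) -> int:
    """Number of markers that belong to some complete-LD subset."""
    return int(sum(s.size for s in subsets))
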