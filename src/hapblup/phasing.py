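"""Haplotype frequency inference within complete-LD marker subsets.

Population haplotype frequencies inside each subset are estimated from
unphased genotypes by maximum-likelihood EM over the multinomial
haplotype-pair likelihood (Excoffier–Slatkin gene counting): the E-step
distributes every phase-ambiguous genotype over its compatible ordered
haplotype pairs proportionally to current frequency products, the M-step
re-estimates frequencies as expected haplotype counts over 2n. Each
individual is then assigned its most probable haplotype pair, and rare
haplotypes (population frequency below 1% by default) are flagged for
omission from the downstream design matrix.

Subsets here are short (the selection stage rarely yields more than 8
SNPs), so the compatible-haplotype space is enumerated exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DiplotypeAssignment, GenotypeDataset, LDSubset, SubsetCatalog
from .errors import ModelError, ValidationError

DEFAULT_FREQ_THRESHOLD = 0.01
DEFAULT_EM_TOL = 1e-8
DEFAULT_EM_MAX_ITER = 1000
DEFAULT_MAX_SUBSET_SIZE = 12
DEFAULT_EM_RESTARTS = 10

_PRUNE_EPS = 1e-12
_RESTART_SEED = 181  # fixed: restarts are deterministic across runs


def _compatible_pairs(genotype: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs consistent with one genotype vector."""
    genotype = np.asarray(genotype)
    if not np.isin(genotype, (0, 1, 2)).all():
        raise ValidationError(f"genotype dosages outside {{0,1,2}}: {genotype.tolist()}")
    het = np.flatnonzero(genotype == 1)
    base = (genotype // 2).astype(np.int8)
    if het.size == 0:
        h = tuple(int(x) for x in base)
        return [(h, h)]
    pairs: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    for bits in range(1 << het.size):
        h1 = base.copy()
        h2 = base.copy()
        for k, pos in enumerate(het):
            if (bits >> k) & 1:
                h1[pos] = 1
            else:
                h2[pos] = 1
        a = tuple(int(x) for x in h1)
        b = tuple(int(x) for x in h2)
        pairs.add((a, b) if a <= b else (b, a))
    return sorted(pairs)


def _em_run(freqs, pair_idx, pair_mult, counts, n, tol, max_iter):
    """One EM run from a given frequency vector; returns (freqs, trace,
    converged, n_iter). The log-likelihood must never decrease."""
    H = freqs.size
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(H)
        loglik = 0.0
        for g, (pi, mult) in enumerate(zip(pair_idx, pair_mult)):
            mass = freqs[pi[:, 0]] * freqs[pi[:, 1]] * mult
            total = mass.sum()
            if total <= 0:
                raise ModelError("EM reached a state assigning zero mass to an observed genotype")
            loglik += counts[g] * np.log(total)
            post = mass / total
            np.add.at(expected, pi[:, 0], counts[g] * post)
            np.add.at(expected, pi[:, 1], counts[g] * post)
        if trace and loglik < trace[-1] - 1e-8:
            raise ModelError(
                f"EM log-likelihood decreased ({trace[-1]:.10g} -> {loglik:.10g})"
            )
        delta = loglik - trace[-1] if trace else np.inf
        trace.append(float(loglik))
        freqs = expected / (2.0 * n)
        if abs(delta) < tol:
            converged = True
            break
    return freqs, np.array(trace), converged, it


def em_haplotype_frequencies(
    genotypes: np.ndarray,
    subset: LDSubset | None = None,
    init: np.ndarray | None = None,
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
    max_subset_size: int = DEFAULT_MAX_SUBSET_SIZE,
    n_restarts: int = DEFAULT_EM_RESTARTS,
) -> SubsetCatalog:
    """ML haplotype frequencies for one subset from unphased genotypes.

    Parameters
    ----------
    genotypes
        (n_individuals, L) dosage matrix restricted to the subset's markers.
    subset
        Optional provenance, stored on the catalog.
    init
        Initial frequencies aligned with the catalog's lexicographically
        ordered candidate haplotypes; when given, a single EM run from this
        start is performed (no restarts). The default start is the
        normalised product of single-marker allele frequencies.
    n_restarts
        Extra EM runs from seeded Dirichlet starting points when phase is
        ambiguous. The multinomial haplotype-pair likelihood has local
        maxima on small samples, so the run ending at the highest
        log-likelihood is kept; the restart seed is fixed, keeping results
        deterministic across calls.

    The candidate space is restricted to haplotypes compatible with at least
    one observed genotype. The observed-data log-likelihood is checked to be
    non-decreasing on every iteration; haplotypes whose final frequency
    vanishes are pruned from the catalog.
    """
    genotypes = np.asarray(genotypes)
    n, length = genotypes.shape
    if length > max_subset_size:
        raise ValidationError(
            f"subset of {length} SNPs exceeds the enumeration cap of {max_subset_size}"
        )
    if n == 0:
        raise ValidationError("no individuals")

    patterns, counts = np.unique(genotypes, axis=0, return_counts=True)
    pair_lists = [_compatible_pairs(p) for p in patterns]

    catalog = sorted({h for pairs in pair_lists for pair in pairs for h in pair})
    index = {h: i for i, h in enumerate(catalog)}
    H = len(catalog)
    pair_idx = [
        np.array([[index[a], index[b]] for a, b in pairs], dtype=np.int64)
        for pairs in pair_lists
    ]
    # multiplicity 2 for heterozygous (ordered) pairs, 1 for homozygous
    pair_mult = [
        np.where(pi[:, 0] != pi[:, 1], 2.0, 1.0) for pi in pair_idx
    ]

    if init is not None:
        start = np.asarray(init, dtype=np.float64)
        if start.shape != (H,):
            raise ValidationError(f"init must have length {H} (candidate haplotypes)")
        starts = [start / start.sum()]
    else:
        allele_freq = genotypes.mean(axis=0) / 2.0
        hap_arr = np.array(catalog, dtype=np.float64)
        products = np.prod(np.where(hap_arr == 1, allele_freq, 1.0 - allele_freq), axis=1)
        total = products.sum()
        starts = [products / total if total > 0 else np.full(H, 1.0 / H)]
        # restarts only matter when some genotype is phase-ambiguous
        if any(len(p) > 1 for p in pair_lists):
            rng = np.random.default_rng(_RESTART_SEED)
            starts += [rng.dirichlet(np.ones(H)) for _ in range(n_restarts)]

    best = None
    for start in starts:
        run = _em_run(start.copy(), pair_idx, pair_mult, counts, n, tol, max_iter)
        if best is None or run[1][-1] > best[1][-1] + 1e-9:
            best = run
    freqs, trace, converged, it = best

    keep = freqs > _PRUNE_EPS
    haplotypes = np.array([catalog[i] for i in np.flatnonzero(keep)], dtype=np.int8)
    freqs = freqs[keep]

    return SubsetCatalog(
        subset=subset,
        haplotypes=haplotypes,
        frequencies=freqs,
        retained=np.ones(freqs.size, dtype=bool),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )


def assign_diplotypes(genotypes: np.ndarray, catalog: SubsetCatalog) -> DiplotypeAssignment:
    """Most probable haplotype pair per individual under catalog frequencies.

    For each individual the compatible unordered pair (h1, h2) maximising
    freq(h1) * freq(h2) * (2 if h1 != h2 else 1) is selected; the posterior
    is that mass over the total compatible mass. Exact ties go to the
    lexicographically smallest pair. Individuals whose every compatible
    pair has zero frequency mass fall back to a uniform choice over the
    compatible pairs present in the catalog and are flagged.
    """
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    index = {tuple(int(x) for x in h): i for i, h in enumerate(catalog.haplotypes)}
    freqs = catalog.frequencies

    pairs_out = np.zeros((n, 2), dtype=np.int64)
    posterior = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)

    cache: dict[tuple[int, ...], tuple[int, int, float, bool]] = {}
    for i in range(n):
        key = tuple(int(x) for x in genotypes[i])
        if key not in cache:
            pairs = _compatible_pairs(genotypes[i])
            known = [(a, b) for a, b in pairs if a in index and b in index]
            if not known:
                raise ModelError(
                    f"genotype {list(key)} has no compatible pair in the haplotype catalog"
                )
            masses = np.array(
                [freqs[index[a]] * freqs[index[b]] * (2.0 if a != b else 1.0) for a, b in known]
            )
            total = masses.sum()
            if total > 0:
                best = int(np.flatnonzero(masses == masses.max())[0])  # lex smallest on tie
                a, b = known[best]
                cache[key] = (index[a], index[b], float(masses[best] / total), False)
            else:
                a, b = known[0]
                cache[key] = (index[a], index[b], 1.0 / len(known), True)
        i1, i2, post, flag = cache[key]
        pairs_out[i] = (min(i1, i2), max(i1, i2))
        posterior[i] = post
        flagged[i] = flag

    # hard invariant: the assigned pair reproduces the observed dosages
    recon = catalog.haplotypes[pairs_out[:, 0]] + catalog.haplotypes[pairs_out[:, 1]]
    if not np.array_equal(recon, genotypes):
        raise ModelError("assigned diplotype does not reproduce the observed dosages")

    return DiplotypeAssignment(pairs=pairs_out, posterior=posterior, flagged=flagged)


def filter_haplotypes_by_frequency(
    catalogs: list[SubsetCatalog], threshold: float = DEFAULT_FREQ_THRESHOLD
) -> pd.DataFrame:
    """Flag haplotypes below the population-frequency threshold.

    Haplotypes with frequency *lower than* the threshold are omitted, so
    equality is retained. Mutates the ``retained`` flags in place and
    returns the per-(chromosome, haplotype length) count table of inferred
    and retained haplotypes.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValidationError(f"frequency threshold must lie in [0, 1), got {threshold}")
    for cat in catalogs:
        cat.retained = cat.frequencies >= threshold
    return haplotype_count_table(catalogs)


def haplotype_count_table(catalogs: list[SubsetCatalog]) -> pd.DataFrame:
    """Counts of inferred and retained haplotypes by chromosome and length."""
    rows = []
    for cat in catalogs:
        chrom = cat.subset.chrom if cat.subset is not None else "?"
        length = cat.haplotypes.shape[1] if cat.n_haplotypes else 0
        rows.append(
            {
                "chrom": chrom,
                "length": length,
                "n_haplotypes": cat.n_haplotypes,
                "n_retained": cat.n_retained,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "length", "n_haplotypes", "n_retained"])
    df = pd.DataFrame(rows)
    out = df.groupby(["chrom", "length"], as_index=False)[["n_haplotypes", "n_retained"]].sum()
    return out.sort_values(["chrom", "length"]).reset_index(drop=True)


def phase_subsets(
    dataset: GenotypeDataset,
    subsets: list[LDSubset],
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
) -> tuple[list[SubsetCatalog], list[DiplotypeAssignment]]:
    """Run EM and diplotype assignment over every LD subset."""
    catalogs: list[SubsetCatalog] = []
    assignments: list[DiplotypeAssignment] = []
    for subset in subsets:
        genotypes = dataset.dosages[:, subset.members]
        cat = em_haplotype_frequencies(genotypes, subset=subset, tol=tol, max_iter=max_iter)
        catalogs.append(cat)
        assignments.append(assign_diplotypes(genotypes, cat))
    return catalogs, assignments
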