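"""Linear models for breeding-value prediction.

Four models over the phenotypes y of the n training individuals:

* FM  — fixed haplotype effects: y = 1 mu + X g + e, solved by
  minimum-norm least squares (X is rank-deficient by construction, since
  each complete subset's columns sum to twice the intercept).
* RM1 — random haplotype effects with homogeneous prior variance,
  Var(g_k) = sigma2_g.
* RM2 — random haplotype effects with heterogeneous prior variance
  scaled by the haplotype's subset, Var(g_k) = sigma2_g * s_k with
  s_k = L_k / m_k (subset length over retained-haplotype count) by default.
* AM  — pedigree animal model, g ~ N(0, A sigma2_g) with A the numerator
  relationship matrix.

Random models are solved through Henderson's mixed-model equations; the
breeding value of an individual under the haplotype models is the sum of
its carried haplotype effects (its design row times g-hat), and under the
animal model its polygenic BLUP. Variance components are estimated by
restricted maximum likelihood on the single-genetic-component model,
maximising the profiled restricted likelihood over the variance ratio on
the spectrum of the genetic covariance kernel.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

from .datatypes import (
    DiplotypeAssignment,
    GenotypeDataset,
    HaplotypeDesign,
    ModelFit,
    Pedigree,
    SubsetCatalog,
    VarianceComponents,
)
from .errors import ModelError, ValidationError

REML_MIN_LOG10_RATIO = -10.0
REML_MAX_LOG10_RATIO = 10.0
VARIANCE_FLOOR_FRACTION = 1e-8


# ---------------------------------------------------------------------------
# design and relationship matrices


def build_design(
    dataset: GenotypeDataset,
    catalogs: list[SubsetCatalog],
    assignments: list[DiplotypeAssignment],
) -> HaplotypeDesign:
    """Individuals x retained-haplotypes copy-count matrix.

    Entry (i, k) counts how many of individual i's two assigned haplotypes
    at haplotype k's subset equal haplotype k. Dropped (rare) haplotypes
    contribute no column: an individual carrying one simply has that copy
    unrepresented, so its subset-column sum falls below 2.
    """
    if len(catalogs) != len(assignments):
        raise ValidationError("catalogs and assignments differ in length")
    n = dataset.n_individuals

    col_subset: list[int] = []
    col_hap: list[int] = []
    col_label: list[str] = []
    col_length: list[int] = []
    col_m: list[int] = []
    columns: list[np.ndarray] = []

    for s, (cat, assign) in enumerate(zip(catalogs, assignments)):
        if assign.pairs.shape[0] != n:
            raise ValidationError(f"subset {s}: diplotypes cover {assign.pairs.shape[0]} of {n}")
        if assign.pairs.max(initial=-1) >= cat.n_haplotypes:
            raise ModelError(f"subset {s}: diplotype references a haplotype outside the catalog")
        length = cat.haplotypes.shape[1]
        m = cat.n_retained
        labels = cat.labels()
        for h in np.flatnonzero(cat.retained):
            copies = (assign.pairs == h).sum(axis=1).astype(np.float64)
            columns.append(copies)
            col_subset.append(s)
            col_hap.append(int(h))
            col_label.append(labels[h])
            col_length.append(length)
            col_m.append(m)

    matrix = np.column_stack(columns) if columns else np.zeros((n, 0))
    return HaplotypeDesign(
        row_ids=dataset.ids.copy(),
        matrix=matrix,
        col_subset=np.array(col_subset, dtype=np.int64),
        col_hap=np.array(col_hap, dtype=np.int64),
        col_label=col_label,
        col_length=np.array(col_length, dtype=np.int64),
        col_n_retained=np.array(col_m, dtype=np.int64),
    )


def rm2_scale_factors(design: HaplotypeDesign, mode: str = "length_over_count") -> np.ndarray:
    """Per-column prior-variance scales for the heterogeneous model.

    ``length_over_count`` (default): s_k = L_k / m_k; ``length``: s_k = L_k;
    ``none``: all ones (reduces RM2 to RM1).
    """
    if mode == "length_over_count":
        return design.col_length / design.col_n_retained
    if mode == "length":
        return design.col_length.astype(np.float64)
    if mode == "none":
        return np.ones(design.n_columns)
    raise ValidationError(f"unknown RM2 scale mode {mode!r}")


def build_numerator_relationship(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method.

    For individual j with parents (s, d): a(i, j) = (a(i, s) + a(i, d)) / 2
    for every earlier i, and a(j, j) = 1 + a(s, d) / 2; unknown parents
    contribute zero. Rows/columns follow pedigree order.
    """
    pedigree.validate()
    n = len(pedigree)
    sidx, didx = pedigree.parent_indices()
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sidx[j], didx[j]
        if j > 0:
            upper = np.zeros(j)
            if s >= 0:
                upper += A[:j, s]
            if d >= 0:
                upper += A[:j, d]
            upper *= 0.5
            A[:j, j] = upper
            A[j, :j] = upper
        inbreeding = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[j, j] = 1.0 + inbreeding
    return A


def incidence_matrix(pedigree: Pedigree, phenotyped_ids: np.ndarray) -> np.ndarray:
    """0/1 matrix mapping phenotype records onto pedigree positions."""
    index = pedigree.index
    n = len(pedigree)
    Z = np.zeros((len(phenotyped_ids), n))
    for row, ind in enumerate(phenotyped_ids):
        if int(ind) not in index:
            raise ValidationError(f"phenotyped individual {ind} absent from the pedigree")
        Z[row, index[int(ind)]] = 1.0
    return Z


# ---------------------------------------------------------------------------
# model fits


def fit_fixed_model(
    y: np.ndarray,
    X: np.ndarray,
    X_full: np.ndarray | None = None,
    ids: np.ndarray | None = None,
) -> ModelFit:
    """Fixed haplotype effects by minimum-norm least squares.

    The design [1 X] is rank-deficient whenever a subset keeps all its
    haplotypes (the subset's columns sum to 2), so the pseudo-inverse
    solution is used: among all least-squares solutions it has minimum
    norm, which keeps "sum of haplotype effects" well defined for every
    individual. Residual variance is RSS / (n - rank).
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    n = y.size
    if n < 2:
        raise ModelError("need at least 2 phenotyped individuals")
    if X.shape[0] != n:
        raise ModelError(f"design has {X.shape[0]} rows for {n} phenotypes")
    if X_full is None:
        X_full = X

    W = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(W, y, rcond=1e-10)
    mu, g = float(coef[0]), coef[1:]
    fitted = W @ coef
    rss = float(np.sum((y - fitted) ** 2))
    dof = n - rank
    sigma2_e = rss / dof if dof > 0 else float("nan")

    bv = X_full @ g
    return ModelFit(
        model="FM",
        mu=mu,
        effects=g,
        variance_components=VarianceComponents(
            sigma2_g=0.0, sigma2_e=sigma2_e, method="least-squares"
        ),
        breeding_values=bv,
        predicted_phenotypes=mu + bv,
        individual_ids=ids if ids is not None else np.arange(X_full.shape[0]),
        extra={"rank": int(rank), "rss": rss},
    )


def _solve_mme(
    y: np.ndarray, W: np.ndarray, penalty: np.ndarray
) -> tuple[float, np.ndarray]:
    """Solve [n 1'W; W'1 W'W + penalty][mu; g] = [1'y; W'y]."""
    n, q = W.shape
    C = np.empty((q + 1, q + 1))
    C[0, 0] = n
    C[0, 1:] = W.sum(axis=0)
    C[1:, 0] = C[0, 1:]
    C[1:, 1:] = W.T @ W + penalty
    rhs = np.concatenate(([y.sum()], W.T @ y))
    try:
        sol = sla.cho_solve(sla.cho_factor(C, lower=True), rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - PD for lambda > 0
        raise ModelError(f"mixed-model equations singular: {exc}") from exc
    return float(sol[0]), sol[1:]


def fit_random_model(
    y: np.ndarray,
    X: np.ndarray,
    scale_factors: np.ndarray | None = None,
    variance_components: VarianceComponents | None = None,
    X_full: np.ndarray | None = None,
    ids: np.ndarray | None = None,
    model: str | None = None,
) -> ModelFit:
    """Random haplotype effects via Henderson's mixed-model equations.

    Prior Var(g_k) = sigma2_g * s_k; ``scale_factors`` of None means the
    homogeneous model (all s_k = 1). With lambda = sigma2_e / sigma2_g the
    equations are [n 1'X; X'1 X'X + lambda D][mu; g] = [1'y; X'y], where
    D = diag(1 / s_k). Components are REML-estimated when not supplied.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    n, q = X.shape
    if y.size != n:
        raise ModelError(f"design has {n} rows for {y.size} phenotypes")
    if X_full is None:
        X_full = X
    s = np.ones(q) if scale_factors is None else np.asarray(scale_factors, dtype=np.float64)
    if s.shape != (q,) or np.any(s <= 0):
        raise ModelError("scale factors must be positive, one per design column")

    if variance_components is None:
        variance_components = estimate_variance_components(y, design=X, scale_factors=s)
    lam = variance_components.ratio
    if not np.isfinite(lam) or lam <= 0:
        raise ModelError(f"variance ratio lambda must be positive and finite, got {lam}")

    mu, g = _solve_mme(y, X, lam * np.diag(1.0 / s))
    bv = X_full @ g
    return ModelFit(
        model=model or ("RM1" if scale_factors is None else "RM2"),
        mu=mu,
        effects=g,
        variance_components=variance_components,
        breeding_values=bv,
        predicted_phenotypes=mu + bv,
        individual_ids=ids if ids is not None else np.arange(X_full.shape[0]),
        extra={"lambda": float(lam), "scale_factors": s},
    )


def fit_animal_model(
    y: np.ndarray,
    pedigree: Pedigree,
    phenotyped_ids: np.ndarray,
    A: np.ndarray | None = None,
    variance_components: VarianceComponents | None = None,
) -> ModelFit:
    """Pedigree animal model y = 1 mu + Z g + e with g ~ N(0, A sigma2_g).

    Breeding values are defined for every pedigree individual, phenotyped
    or not, through the relationship matrix. A^-1 enters the equations by
    factorising A and solving, with no structural shortcuts, so inbred
    pedigrees are handled exactly.
    """
    y = np.asarray(y, dtype=np.float64)
    if A is None:
        A = build_numerator_relationship(pedigree)
    n_ped = len(pedigree)
    if A.shape != (n_ped, n_ped):
        raise ModelError("relationship matrix does not match the pedigree")
    Z = incidence_matrix(pedigree, phenotyped_ids)
    if y.size != Z.shape[0]:
        raise ModelError("phenotype vector and id list differ in length")

    if variance_components is None:
        kernel = Z @ A @ Z.T
        variance_components = estimate_variance_components(y, kernel=kernel)
    lam = variance_components.ratio
    if not np.isfinite(lam) or lam <= 0:
        raise ModelError(f"variance ratio lambda must be positive and finite, got {lam}")

    A_inv = sla.cho_solve(sla.cho_factor(A, lower=True), np.eye(n_ped))
    mu, g = _solve_mme(y, Z, lam * A_inv)
    return ModelFit(
        model="AM",
        mu=mu,
        effects=g,
        variance_components=variance_components,
        breeding_values=g,
        predicted_phenotypes=mu + g,
        individual_ids=pedigree.ids.copy(),
        extra={"lambda": float(lam)},
    )


# ---------------------------------------------------------------------------
# variance components


def estimate_variance_components(
    y: np.ndarray,
    design: np.ndarray | None = None,
    scale_factors: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
) -> VarianceComponents:
    """REML estimates of (sigma2_g, sigma2_e) for one genetic component.

    The model is y = 1 mu + u + e with u ~ N(0, sigma2_g K) and
    e ~ N(0, sigma2_e I), where K is either supplied directly (``kernel``)
    or formed as X diag(s) X' from the design and scale factors. The
    intercept is projected out with an orthonormal basis, K's spectrum in
    that complement is computed once, and the restricted likelihood —
    profiled over sigma2_e — is maximised over the variance ratio
    r = sigma2_g / sigma2_e by bracketed 1-D search on log r. Estimates
    are deterministic; sigma2_g is floored at 1e-8 * Var(y).
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 3:
        raise ModelError("need at least 3 observations to separate two variances")
    if kernel is None:
        if design is None:
            raise ModelError("supply either a design matrix or a covariance kernel")
        X = np.asarray(design, dtype=np.float64)
        s = np.ones(X.shape[1]) if scale_factors is None else np.asarray(scale_factors)
        kernel = (X * s) @ X.T
    if kernel.shape != (n, n):
        raise ModelError("kernel must be n x n")

    # orthonormal basis of the complement of the intercept
    Q, _ = np.linalg.qr(np.ones((n, 1)), mode="complete")
    B = Q[:, 1:]
    xi, U = np.linalg.eigh(B.T @ kernel @ B)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (B.T @ y)
    eta2 = eta**2
    m = n - 1

    def neg_restricted_ll(log10_r: float) -> float:
        r = 10.0**log10_r
        w = r * xi + 1.0
        sigma2_e = float(np.sum(eta2 / w) / m)
        return float(np.sum(np.log(w)) + m * np.log(max(sigma2_e, 1e-300)))

    grid = np.linspace(REML_MIN_LOG10_RATIO, REML_MAX_LOG10_RATIO, 161)
    values = [neg_restricted_ll(g) for g in grid]
    k = int(np.argmin(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
    best = float(res.x) if res.fun <= values[k] else float(grid[k])

    r = 10.0**best
    w = r * xi + 1.0
    sigma2_e = float(np.sum(eta2 / w) / m)
    sigma2_g = r * sigma2_e
    floor = VARIANCE_FLOOR_FRACTION * float(np.var(y))
    converged = bool(res.success)
    if sigma2_g < floor:
        sigma2_g = floor
    return VarianceComponents(
        sigma2_g=sigma2_g, sigma2_e=sigma2_e, method="spectral-reml", converged=converged
    )
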