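"""Independent reference computations used to check the implementation.

Everything here is deliberately written by a different route than the
package code: brute-force enumeration, dense closed-form algebra, grid
search, or direct likelihood evaluation.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.optimize import minimize


def pedigree_order_ok(ids, sires, dams) -> bool:
    """Linear scan: every parent appears earlier than its offspring."""
    seen = set()
    for i, s, d in zip(ids, sires, dams):
        for p in (s, d):
            if p != 0 and p not in seen:
                return False
        seen.add(i)
    return True


def has_cycle(ids, sires, dams) -> bool:
    """Depth-first ancestry walk looking for an individual among its ancestors."""
    parents = {i: [p for p in (s, d) if p != 0] for i, s, d in zip(ids, sires, dams)}

    def ancestors(i, seen):
        for p in parents.get(i, []):
            if p in seen:
                return True
            if ancestors(p, seen | {p}):
                return True
        return False

    return any(ancestors(i, {i}) for i in parents)


# ---------------------------------------------------------------------------
# haplotype likelihood


def _pair_mass_matrices(genotypes: np.ndarray, haplotypes: np.ndarray) -> list[np.ndarray]:
    """Per genotype: (H, H) matrix with HWE pair multiplicities (0/1/2)."""
    H = len(haplotypes)
    sums = haplotypes[:, None, :] + haplotypes[None, :, :]  # (H, H, L)
    out = []
    for g in genotypes:
        compat = (sums == g).all(axis=2)
        M = np.where(compat, 2.0, 0.0)
        np.fill_diagonal(M, np.where(np.diag(compat), 1.0, 0.0))
        out.append(M)
    return out


def genotype_loglik(freqs: np.ndarray, genotypes: np.ndarray, haplotypes: np.ndarray) -> float:
    """Observed-data log-likelihood of unphased genotypes under HWE pairing."""
    ll = 0.0
    iu = np.triu_indices(len(freqs))
    for M in _pair_mass_matrices(np.asarray(genotypes), np.asarray(haplotypes)):
        mass = float((M[iu] * freqs[iu[0]] * freqs[iu[1]]).sum())
        if mass <= 0:
            return -np.inf
        ll += np.log(mass)
    return ll


def ml_haplotype_freqs(genotypes: np.ndarray, n_starts: int = 12, seed: int = 0):
    """Direct ML over the full 2^L haplotype simplex (L <= 3).

    Deterministic multi-start SLSQP on the simplex; returns (haplotypes,
    frequencies, loglik) at the best optimum found.
    """
    genotypes = np.asarray(genotypes)
    L = genotypes.shape[1]
    haplotypes = np.array(list(product((0, 1), repeat=L)), dtype=np.int8)
    H = len(haplotypes)
    matrices = _pair_mass_matrices(genotypes, haplotypes)
    iu = np.triu_indices(H)
    flat = np.stack([M[iu] for M in matrices])  # (n_geno, n_pairs)

    def negll(f):
        f = np.clip(f, 0.0, None)
        mass = flat @ (f[iu[0]] * f[iu[1]])
        if (mass <= 0).any():
            return 1e12
        return -float(np.log(mass).sum())

    rng = np.random.default_rng(seed)
    starts = [np.full(H, 1.0 / H)] + [rng.dirichlet(np.ones(H)) for _ in range(n_starts - 1)]
    best_f, best_nll = None, np.inf
    constraints = [{"type": "eq", "fun": lambda f: f.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * H
    for x0 in starts:
        res = minimize(negll, x0, method="SLSQP", bounds=bounds, constraints=constraints,
                       options={"maxiter": 500, "ftol": 1e-14})
        f = np.clip(res.x, 0.0, None)
        f /= f.sum()
        nll = negll(f)
        if nll < best_nll:
            best_nll, best_f = nll, f
    return haplotypes, best_f, -best_nll


# ---------------------------------------------------------------------------
# mixed-model closed forms


def blup_oracle(y, W, G, sigma2_g, sigma2_e):
    """GLS mean and BLUP effects from the dense variance formulation.

    y = 1 mu + W g + e with Var(g) = sigma2_g G, Var(e) = sigma2_e I.
    Returns (mu_hat, g_hat) via V = sigma2_g W G W' + sigma2_e I.
    """
    y = np.asarray(y, float)
    n = y.size
    ones = np.ones(n)
    V = sigma2_g * W @ G @ W.T + sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    mu = float(ones @ Vi @ y / (ones @ Vi @ ones))
    g = sigma2_g * G @ W.T @ Vi @ (y - mu * ones)
    return mu, g


def projection_fit(y, W):
    """Least-squares fitted values via an orthonormal basis of col(W)."""
    from scipy.linalg import orth

    Q = orth(W)
    return Q @ (Q.T @ y)


def restricted_loglik(y, K, sigma2_g, sigma2_e):
    """REML log-likelihood (up to a constant) of y = 1 mu + u + e."""
    y = np.asarray(y, float)
    n = y.size
    X = np.ones((n, 1))
    V = sigma2_g * K + sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * (ld_v + ld_x + float(r @ Vi @ r))


def grid_reml(y, K, grid):
    """Arg-max of the restricted likelihood over a 2-D variance grid."""
    best, best_ll = None, -np.inf
    for sg in grid:
        for se in grid:
            ll = restricted_loglik(y, K, sg, se)
            if ll > best_ll:
                best_ll, best = ll, (sg, se)
    return best


def tabular_a_by_hand(parents: dict[int, tuple[int, int]]) -> np.ndarray:
    """Wright's recursion applied literally, dict-based, ids 1..n in order."""
    ids = sorted(parents)
    n = len(ids)
    A = {}

    def a(i, j):
        if i == 0 or j == 0:
            return 0.0
        if i > j:
            i, j = j, i
        if (i, j) in A:
            return A[(i, j)]
        s, d = parents[j]
        if i == j:
            val = 1.0 + 0.5 * a(s, d)
        else:
            val = 0.5 * (a(i, s) + a(i, d))
        A[(i, j)] = val
        return val

    out = np.zeros((n, n))
    for i in ids:
        for j in ids:
            out[i - 1, j - 1] = a(i, j)
    return out
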