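"""Independent brute-force oracles.

Definitional implementations (explicit loops, Floyd-Warshall, direct
likelihood maximization) kept deliberately separate from the package's
algorithms so equivalence tests compare two routes to the same quantity.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# shortest paths / efficiency


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the triple loop; 0 length = no edge."""
    n = lengths.shape[0]
    dist = np.full((n, n), np.inf)
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                dist[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def _edge_lengths(w: np.ndarray, variant: str) -> np.ndarray:
    if variant == "binary":
        return (w > 0).astype(float)
    lengths = np.zeros_like(w, dtype=float)
    lengths[w > 0] = 1.0 / w[w > 0]
    return lengths


def global_efficiency_bf(w: np.ndarray, variant: str) -> float:
    n = w.shape[0]
    dist = floyd_warshall(_edge_lengths(w, variant))
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def local_efficiency_bf(w: np.ndarray, variant: str) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for u in range(n):
        neigh = [v for v in range(n) if w[u, v] > 0]
        k = len(neigh)
        if k < 2:
            continue
        sub = w[np.ix_(neigh, neigh)]
        dist = floyd_warshall(_edge_lengths(sub, variant))
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a == b or not np.isfinite(dist[a, b]) or dist[a, b] == 0:
                    continue
                inv = 1.0 / dist[a, b]
                if variant == "binary":
                    acc += inv
                else:
                    acc += (w[u, neigh[a]] * w[u, neigh[b]] * inv) ** (1.0 / 3.0)
        out[u] = acc / (k * (k - 1))
    return out


def modularity_bf(w: np.ndarray, labels: np.ndarray) -> float:
    """Definitional double sum (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta."""
    n = w.shape[0]
    k = w.sum(axis=1)
    m2 = k.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / m2
    return q / m2


def participation_bf(w: np.ndarray, labels: np.ndarray, variant: str) -> np.ndarray:
    conn = (w > 0).astype(float) if variant == "binary" else w
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        kappa = conn[i].sum()
        if kappa == 0:
            continue
        acc = 0.0
        for m in np.unique(labels):
            acc += (conn[i, labels == m].sum() / kappa) ** 2
        out[i] = 1.0 - acc
    return out


def random_symmetric_graph(
    rng: np.random.Generator, n: int, weighted: bool, edge_prob: float = 0.5
) -> np.ndarray:
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                w[i, j] = w[j, i] = rng.uniform(0.1, 1.0) if weighted else 1.0
    return w


# ---------------------------------------------------------------------------
# haplotype likelihood


def haplotype_loglik(freqs: np.ndarray, dose_counts: dict[tuple[int, int], int]) -> float:
    """Multinomial log-likelihood of two-marker genotype classes.

    ``dose_counts`` maps (copies of first allele at marker 1, at marker 2)
    to subject counts; haplotypes are ordered as in the package:
    (1,1), (1,0), (0,1), (0,0).
    """
    haps = [(1, 1), (1, 0), (0, 1), (0, 0)]
    ll = 0.0
    for (g1, g2), count in dose_counts.items():
        prob = 0.0
        for a in range(4):
            for b in range(a, 4):
                if haps[a][0] + haps[b][0] == g1 and haps[a][1] + haps[b][1] == g2:
                    p = freqs[a] * freqs[b]
                    prob += 2 * p if a != b else p
        ll += count * np.log(max(prob, 1e-300))
    return ll


def maximize_haplotype_likelihood(dose_counts: dict[tuple[int, int], int]) -> np.ndarray:
    """Direct constrained maximization over the 3-simplex (SLSQP, multistart)."""
    best, best_ll = None, -np.inf
    rng = np.random.default_rng(12345)
    starts = [np.full(4, 0.25)] + [rng.dirichlet(np.ones(4)) for _ in range(5)]
    for x0 in starts:
        res = minimize(
            lambda f: -haplotype_loglik(f, dose_counts),
            x0,
            method="SLSQP",
            bounds=[(1e-9, 1.0)] * 4,
            constraints={"type": "eq", "fun": lambda f: f.sum() - 1.0},
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success and -res.fun > best_ll:
            best_ll, best = -res.fun, res.x
    return best


# ---------------------------------------------------------------------------
# misc numerics


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Slope via the normal equations on the 2-column design."""
    design = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return float(beta[1])


def riemann_auc(curve: np.ndarray, grid: np.ndarray, n_fine: int = 200_000) -> float:
    """Fine-grid Riemann sum of the piecewise-linear interpolant."""
    fine = np.linspace(grid[0], grid[-1], n_fine)
    vals = np.interp(fine, grid, curve)
    return float(np.sum(0.5 * (vals[1:] + vals[:-1]) * np.diff(fine)))
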