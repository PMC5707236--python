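"""Connectivity-matrix construction and proportional thresholding.

Per subject: Pearson correlations between all ROI pairs over the
retained volumes, with correlations zeroed for ROI pairs whose centers
lie less than 20 mm apart (shared non-biological signal between adjacent
spheres) and on the diagonal.  The raw matrix is then thresholded over a
grid of proportional densities (default 1%..30% in 1% steps): at density
tau the round(tau * N(N-1)/2) largest-valued edges are retained, giving
one weighted and one binary graph per density.  Edge sets are nested
across densities by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivityStack",
    "ConstructionError",
    "ConstructionWarning",
    "build_stack",
    "correlation_matrix",
    "default_density_grid",
    "proportional_threshold",
    "roi_distances",
]


class ConstructionError(ValueError):
    """Invalid input to network construction."""


class ConstructionWarning(UserWarning):
    """Non-fatal conditions: constant ROI series, exhausted positive edges."""


def default_density_grid() -> np.ndarray:
    """The standard density grid: 0.01 to 0.30 in steps of 0.01."""
    return np.round(np.arange(1, 31) / 100.0, 2)


def roi_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between ROI centers (mm)."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def correlation_matrix(
    data: np.ndarray,
    coords: np.ndarray | None = None,
    min_distance_mm: float = 20.0,
) -> np.ndarray:
    """Pearson correlation matrix with distance and diagonal zeroing.

    ``data`` is retained volumes x ROIs.  Pairs closer than
    ``min_distance_mm`` (strict) are set to 0 when coordinates are given.
    Constant ROI series have undefined correlations; their rows/columns
    are set to 0 with a warning rather than aborting the subject.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ConstructionError("need at least 3 retained volumes")
    n = data.shape[1]
    sd = data.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant ROI series; correlations set to 0",
            ConstructionWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data.T)
    r = np.nan_to_num(r, nan=0.0)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape[0] != n:
            raise ConstructionError("coordinate count does not match ROI count")
        r[roi_distances(coords) < min_distance_mm] = 0.0
    np.fill_diagonal(r, 0.0)
    return (r + r.T) / 2.0  # enforce exact symmetry


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _ranked_edges(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by value descending, ties by (i, j) lex."""
    n = raw.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    vals = raw[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    return rows[order], cols[order], vals[order]


def proportional_threshold(
    raw: np.ndarray, density: float
) -> tuple[np.ndarray, np.ndarray]:
    """Retain the k = round(density * M) largest edges of a raw matrix.

    M counts all N(N-1)/2 pairs (distance-zeroed pairs simply hold 0 and
    never rank among the strongest).  Edges are ranked by signed value,
    largest first, with ties broken by (row, column) lexicographic order.
    If fewer than k edges have positive weight, only the positive edges
    are kept and a warning is raised.  Returns the (weighted, binary)
    matrix pair.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    if raw.shape != (n, n) or not np.allclose(raw, raw.T):
        raise ConstructionError("raw matrix must be square and symmetric")
    if np.any(np.diag(raw) != 0):
        raise ConstructionError("raw matrix must have a zero diagonal")
    if not (0.0 < density <= 1.0):
        raise ConstructionError(f"density must be in (0, 1], got {density}")
    m = n * (n - 1) // 2
    k = _round_half_away(density * m)
    if k == 0:
        raise ConstructionError(f"density {density} keeps zero edges for {n} nodes")
    rows, cols, vals = _ranked_edges(raw)
    n_positive = int(np.sum(vals > 0))
    if n_positive < k:
        warnings.warn(
            f"only {n_positive} positive edges available for k={k}; keeping all positive edges",
            ConstructionWarning,
            stacklevel=2,
        )
        k = n_positive
        if k == 0:
            raise ConstructionError("no positive edges to retain")
    weighted = np.zeros_like(raw)
    ri, ci = rows[:k], cols[:k]
    weighted[ri, ci] = vals[:k]
    weighted[ci, ri] = vals[:k]
    binary = (weighted != 0).astype(float)
    return weighted, binary


@dataclass
class ConnectivityStack:
    """One subject's raw matrix plus its thresholded versions per density."""

    raw: np.ndarray
    densities: np.ndarray
    weighted: list[np.ndarray]
    binary: list[np.ndarray]

    @property
    def n_nodes(self) -> int:
        return self.raw.shape[0]

    def edge_counts(self) -> np.ndarray:
        return np.array([int(b.sum() // 2) for b in self.binary])


def build_stack(
    raw: np.ndarray,
    densities: np.ndarray | None = None,
    check_nesting: bool = True,
) -> ConnectivityStack:
    """Threshold a raw matrix at every grid density.

    Edges are ranked once; each density keeps a prefix of that ranking,
    so the nesting invariant (edges at lower density are a subset of
    edges at higher density) holds by construction and is verified.
    """
    if densities is None:
        densities = default_density_grid()
    densities = np.asarray(densities, dtype=float)
    if densities.ndim != 1 or len(densities) == 0:
        raise ConstructionError("densities must be a non-empty 1-d grid")
    weighted, binary = [], []
    for tau in densities:
        w, b = proportional_threshold(raw, float(tau))
        weighted.append(w)
        binary.append(b)
    if check_nesting:
        order = np.argsort(densities)
        for a, b in zip(order[:-1], order[1:]):
            lo, hi = binary[a], binary[b]
            if np.any((lo != 0) & (hi == 0)):
                raise AssertionError("edge nesting violated across densities")
    return ConnectivityStack(raw=raw, densities=densities, weighted=weighted, binary=binary)
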