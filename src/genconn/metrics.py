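"""Weighted and binary network measures on thresholded brain graphs.

Implements the measure set used for the association analyses:

* global efficiency — mean inverse shortest-path length over all node
  pairs, with unreachable pairs contributing 0;
* local efficiency — efficiency among each node's neighbours.  The
  weighted variant follows the standard weighted formulation with
  cube-root weighting of the endpoint weights and shortest paths
  confined to the neighbour subgraph;
* maximized modularity — best-of-seeds Louvain (+ fine-tuning) Q on the
  subject graph;
* participation coefficient — P_i = 1 - sum_m (kappa_im / kappa_i)^2
  with kappa the node strength (weighted) or degree (binary).

Weighted shortest paths use connection lengths 1/w.  ``measure_suite``
evaluates the full set across a density grid, producing whole-brain and
per-module curves for both variants in a tidy long-format table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .community import ModulePartition, best_partition

__all__ = [
    "MetricError",
    "global_efficiency",
    "local_efficiency",
    "measure_suite",
    "modularity_max",
    "participation_coefficient",
    "pair_distances",
]

WHOLE_BRAIN_MEASURES = ("global_efficiency", "local_efficiency_mean", "modularity_max")
MODULE_MEASURES = ("local_efficiency", "participation")


class MetricError(ValueError):
    """Invalid input to a network measure."""


def _check(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise MetricError("graph must be a square matrix")
    if np.any(w < 0):
        raise MetricError("graph weights must be nonnegative")
    return w


def _lengths(w: np.ndarray, variant: str) -> np.ndarray:
    if variant == "binary":
        return (w > 0).astype(float)
    if variant == "weighted":
        with np.errstate(divide="ignore"):
            lengths = np.where(w > 0, 1.0 / w, 0.0)
        return lengths
    raise MetricError(f"variant must be 'weighted' or 'binary', got {variant!r}")


def pair_distances(w: np.ndarray, variant: str = "weighted") -> np.ndarray:
    """All-pairs shortest-path distances on connection lengths 1/w
    (unit lengths for the binary variant); absent paths are inf."""
    lengths = _lengths(_check(w), variant)
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def _inverse_distances(dist: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv


def global_efficiency(w: np.ndarray, variant: str = "weighted") -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    w = _check(w)
    n = w.shape[0]
    if n < 2:
        raise MetricError("global efficiency undefined for fewer than 2 nodes")
    inv = _inverse_distances(pair_distances(w, variant))
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(w: np.ndarray, variant: str = "weighted") -> np.ndarray:
    """Per-node local efficiency (efficiency among each node's neighbours).

    Binary: the global efficiency of the subgraph induced by the node's
    neighbours.  Weighted: for node u with neighbour set V,

        E(u) = sum_{j != h in V} (w_uj * w_uh * e_jh)^(1/3) / (k (k - 1))

    where e_jh is the inverse shortest-path length between j and h inside
    the neighbour subgraph (lengths 1/w) and k = |V|.  Nodes with fewer
    than 2 neighbours score 0.
    """
    w = _check(w)
    n = w.shape[0]
    adj = w > 0
    eff = np.zeros(n)
    for u in range(n):
        neigh = np.flatnonzero(adj[u])
        k = len(neigh)
        if k < 2:
            continue
        sub = w[np.ix_(neigh, neigh)]
        lengths = _lengths(sub, "binary" if variant == "binary" else "weighted")
        dist = shortest_path(lengths, method="D", directed=False)
        e = _inverse_distances(dist)
        if variant == "binary":
            eff[u] = e.sum() / (k * (k - 1))
        else:
            wu = np.cbrt(w[u, neigh])
            eff[u] = float((np.outer(wu, wu) * np.cbrt(e)).sum()) / (k * (k - 1))
    return eff


def participation_coefficient(
    w: np.ndarray, labels: np.ndarray, variant: str = "weighted"
) -> np.ndarray:
    """Participation coefficient per node.

    P_i = 1 - sum_m (kappa_im / kappa_i)^2 where kappa is strength
    (weighted) or degree (binary); nodes with no connections score 0.
    """
    w = _check(w)
    labels = np.asarray(labels)
    if labels.shape[0] != w.shape[0]:
        raise MetricError("partition does not cover every node")
    conn = (w > 0).astype(float) if variant == "binary" else w
    c = int(labels.max()) + 1
    onehot = np.zeros((w.shape[0], c))
    onehot[np.arange(w.shape[0]), labels] = 1.0
    kappa_im = conn @ onehot
    kappa = conn.sum(axis=1)
    p = np.zeros(w.shape[0])
    nz = kappa > 0
    p[nz] = 1.0 - ((kappa_im[nz] / kappa[nz, None]) ** 2).sum(axis=1)
    return p


def modularity_max(w: np.ndarray, n_seeds: int = 10, base_seed: int = 0) -> float:
    """Maximized modularity: best-of-seeds Louvain + fine-tuning Q."""
    return best_partition(w, n_seeds=n_seeds, base_seed=base_seed).q


def measure_suite(
    stack,
    partition: ModulePartition | np.ndarray,
    variants: tuple[str, ...] = ("weighted", "binary"),
    n_modularity_seeds: int = 10,
    base_seed: int = 0,
    include_modularity: bool = True,
) -> pd.DataFrame:
    """All measures across the density grid, whole-brain and per-module.

    Returns a long-format table with columns density, variant, measure,
    module (empty for whole-brain rows) and value.  Per-module rows hold
    the mean over that module's nodes of local efficiency and of the
    participation coefficient; the fixed group-level partition is reused
    at every density.
    """
    labels = partition.labels if isinstance(partition, ModulePartition) else np.asarray(partition)
    if labels.shape[0] != stack.n_nodes:
        raise MetricError("partition does not cover the stack's nodes")
    modules = np.unique(labels)
    rows = []
    for d_idx, density in enumerate(stack.densities):
        for variant in variants:
            graph = stack.weighted[d_idx] if variant == "weighted" else stack.binary[d_idx]
            eloc = local_efficiency(graph, variant)
            part = participation_coefficient(graph, labels, variant)
            rows.append((density, variant, "global_efficiency", None, global_efficiency(graph, variant)))
            rows.append((density, variant, "local_efficiency_mean", None, float(eloc.mean())))
            if include_modularity:
                rows.append(
                    (density, variant, "modularity_max", None,
                     modularity_max(graph, n_seeds=n_modularity_seeds, base_seed=base_seed))
                )
            for m in modules:
                idx = labels == m
                rows.append((density, variant, "local_efficiency", int(m), float(eloc[idx].mean())))
                rows.append((density, variant, "participation", int(m), float(part[idx].mean())))
    return pd.DataFrame(rows, columns=["density", "variant", "measure", "module", "value"])
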