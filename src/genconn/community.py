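"""Module decomposition of weighted brain graphs.

Implements seeded Louvain optimization of Newman weighted modularity
(two-phase greedy with graph aggregation), a single-node best-move
fine-tuning refinement, best-of-seeds group decomposition, and a
stability criterion for choosing the single density at which the group
partition is derived.

Modularity here is the classic (resolution 1) weighted quantity

    Q = sum_c [ w_cc / 2m - (k_c / 2m)^2 ]

where w_cc sums edge weights inside community c over ordered pairs,
k_c sums node strengths, and 2m is the total weight.  The per-subject
metrics downstream reuse one fixed group-level partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CommunityError",
    "ModulePartition",
    "best_partition",
    "finetune",
    "group_mean_matrix",
    "louvain",
    "modularity_q",
    "normalized_mutual_information",
    "select_optimal_density",
]

_EPS = 1e-12


class CommunityError(ValueError):
    """Invalid input to community detection."""


@dataclass
class ModulePartition:
    """ROI -> module labels with the modularity of the partition."""

    labels: np.ndarray
    q: float
    density: float | None = None
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _check_graph(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise CommunityError("graph must be a square matrix")
    if np.any(w < 0):
        raise CommunityError("graph weights must be nonnegative")
    return w


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous module indices 0..C-1, by first appearance."""
    _, compact = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty_like(compact)
    nxt = 0
    for i, c in enumerate(compact):
        if c not in order:
            order[c] = nxt
            nxt += 1
        out[i] = order[c]
    return out


def modularity_q(w: np.ndarray, labels: np.ndarray) -> float:
    """Newman weighted modularity of a partition.

    Handles aggregated graphs with self-loops (diagonal counts once in
    both the internal weight and the strength).
    """
    w = _check_graph(w)
    labels = np.asarray(labels)
    if labels.shape[0] != w.shape[0]:
        raise CommunityError("label count does not match node count")
    m2 = w.sum()
    if m2 <= 0:
        raise CommunityError("modularity undefined: total weight is zero")
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        q += w[np.ix_(idx, idx)].sum() / m2 - (k[idx].sum() / m2) ** 2
    return float(q)


def _local_move(w: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One Louvain phase: sweep nodes in shuffled order until no move helps.

    ``labels`` is modified in place; slots 0..n-1 serve as community ids
    so an empty slot always offers the new-singleton option (score 0).
    Returns True when at least one move was made.
    """
    n = w.shape[0]
    k = w.sum(axis=1)
    m2 = k.sum()
    sigma_tot = np.bincount(labels, weights=k, minlength=n)
    any_move = False
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            c_old = labels[i]
            w_i = w[i].copy()
            w_i[i] = 0.0  # self-loop contributes equally to every choice
            links = np.bincount(labels, weights=w_i, minlength=n)
            sigma_tot[c_old] -= k[i]
            # score proportional to the modularity gain of joining community c
            scores = links - k[i] * sigma_tot / m2
            best = int(np.argmax(scores))  # ties -> lowest community id
            if scores[best] > scores[c_old] + _EPS:
                labels[i] = best
                sigma_tot[best] += k[i]
                moved = True
                any_move = True
            else:
                sigma_tot[c_old] += k[i]
    return any_move


def _aggregate(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Collapse communities into nodes; internal weight becomes a self-loop."""
    c = labels.max() + 1
    onehot = np.zeros((w.shape[0], c))
    onehot[np.arange(w.shape[0]), labels] = 1.0
    return onehot.T @ w @ onehot


def louvain(w: np.ndarray, seed: int = 0) -> ModulePartition:
    """Two-phase greedy Louvain with seeded node-visit order.

    Modularity never decreases across passes (local moves only accept
    improving moves; aggregation preserves Q).
    """
    w = _check_graph(w)
    if w.sum() <= 0:
        raise CommunityError("cannot partition a graph with zero total weight")
    rng = np.random.default_rng(seed)
    n = w.shape[0]
    final = np.arange(n)
    w_agg = w.copy()
    while True:
        labels = np.arange(w_agg.shape[0])
        moved = _local_move(w_agg, labels, rng)
        labels = _compact_labels(labels)
        final = labels[final]
        if not moved or labels.max() + 1 == w_agg.shape[0]:
            break
        w_agg = _aggregate(w_agg, labels)
    final = _compact_labels(final)
    return ModulePartition(labels=final, q=modularity_q(w, final), seed=seed)


def finetune(w: np.ndarray, partition: ModulePartition | np.ndarray) -> ModulePartition:
    """Greedy single-node best-move refinement.

    Repeatedly considers moving every node to any other module (or a new
    singleton) and applies the single move with the largest positive
    modularity gain, until no improving move exists.  Q never decreases,
    and the move space is finite with strictly increasing Q, so the loop
    terminates.
    """
    w = _check_graph(w)
    labels = partition.labels if isinstance(partition, ModulePartition) else np.asarray(partition)
    labels = _compact_labels(labels.copy())
    k = w.sum(axis=1)
    m2 = k.sum()
    if m2 <= 0:
        raise CommunityError("cannot refine a graph with zero total weight")
    n = w.shape[0]
    while True:
        c = labels.max() + 1
        onehot = np.zeros((n, c))
        onehot[np.arange(n), labels] = 1.0
        links = w @ onehot  # links[i, c] = weight from i to community c
        links[np.arange(n), labels] -= np.diag(w)  # exclude any self-loop
        sigma_tot = k @ onehot
        # score of node i joining community c after removal from its own
        scores = links - np.outer(k, sigma_tot) / m2
        scores[np.arange(n), labels] += k**2 / m2  # own community without i
        # extra column: new singleton community, score 0
        scores = np.hstack([scores, np.zeros((n, 1))])
        own = scores[np.arange(n), labels]
        gains = scores - own[:, None]
        gains[np.arange(n), labels] = 0.0
        i, target = np.unravel_index(np.argmax(gains), gains.shape)
        if gains[i, target] <= _EPS:
            break
        labels[i] = target if target < c else c
        labels = _compact_labels(labels)
    return ModulePartition(labels=labels, q=modularity_q(w, labels))


def best_partition(
    w: np.ndarray,
    n_seeds: int = 50,
    base_seed: int = 0,
    refine: bool = True,
) -> ModulePartition:
    """Best-of-seeds Louvain (+ fine-tuning): highest Q wins, ties to the
    lowest seed."""
    best: ModulePartition | None = None
    for s in range(base_seed, base_seed + n_seeds):
        part = louvain(w, seed=s)
        if refine:
            part = finetune(w, part)
            part.seed = s
        if best is None or part.q > best.q + _EPS:
            best = part
    return best


def group_mean_matrix(raws: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of per-subject raw connectivity matrices."""
    if not raws:
        raise CommunityError("no matrices to average")
    return np.mean(np.stack(raws), axis=0)


def normalized_mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """NMI between two labelings, arithmetic-mean normalization.

    Two all-in-one-cluster labelings agree perfectly (NMI 1); when only
    one is trivial the normalizer is degenerate and the score is 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    na, nb = a.max() + 1, b.max() + 1
    if na == 1 and nb == 1:
        return 1.0
    n = a.shape[0]
    contingency = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / n
    pa = contingency.sum(axis=1)
    pb = contingency.sum(axis=0)
    nz = contingency > 0
    mi = float(np.sum(contingency[nz] * np.log(contingency[nz] / np.outer(pa, pb)[nz])))
    ha = -float(np.sum(pa[pa > 0] * np.log(pa[pa > 0])))
    hb = -float(np.sum(pb[pb > 0] * np.log(pb[pb > 0])))
    denom = 0.5 * (ha + hb)
    return mi / denom if denom > 0 else 0.0


def select_optimal_density(
    stack,
    seeds: tuple[int, ...] = tuple(range(10)),
    strategy=None,
) -> tuple[float, np.ndarray]:
    """Choose the single density for group module decomposition.

    Default strategy: at every candidate density run Louvain (+
    fine-tuning) with a fixed seed set on the group-level graph, then
    score each density by the mean pairwise normalized mutual
    information among all partitions obtained at that density and its
    adjacent grid neighbours.  Densities whose graph leaves nodes with
    no edges are ineligible (an isolated node cannot be assigned to any
    module) unless every density does.  The eligible density with the
    highest stability score wins; ties go to the lowest density.  A
    custom ``strategy`` callable (stack -> density) can be injected
    instead.

    Returns (density, stability score per density in ascending density
    order; ineligible densities score -inf).
    """
    if strategy is not None:
        return strategy(stack), None
    densities = np.asarray(stack.densities, dtype=float)
    if len(densities) < 2:
        raise CommunityError("need at least 2 candidate densities")
    order = np.argsort(densities)
    partitions = []
    degenerate = True
    for idx in order:
        parts = []
        for s in seeds:
            part = finetune(stack.weighted[idx], louvain(stack.weighted[idx], seed=s))
            parts.append(part.labels)
            if part.labels.max() > 0:
                degenerate = False
        partitions.append(parts)
    if degenerate:
        raise CommunityError("all candidate densities yield a single module")
    scores = np.empty(len(order))
    for pos in range(len(order)):
        pool = []
        for adj in (pos - 1, pos, pos + 1):
            if 0 <= adj < len(order):
                pool.extend(partitions[adj])
        total, count = 0.0, 0
        for a in range(len(pool)):
            for b in range(a + 1, len(pool)):
                total += normalized_mutual_information(pool[a], pool[b])
                count += 1
        scores[pos] = total / count
    no_isolates = np.array(
        [not np.any(stack.binary[idx].sum(axis=1) == 0) for idx in order]
    )
    if no_isolates.any():
        scores = np.where(no_isolates, scores, -np.inf)
    best_pos = int(np.argmax(scores))  # argmax ties -> first = lowest density
    return float(densities[order][best_pos]), scores
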