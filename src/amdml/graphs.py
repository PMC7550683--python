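"""Supervised pair sets and graph matrices for discriminative embedding.

For each view the method builds a k-NN intraclass graph G (same-label pairs,
weight 1/|Xs|) and a k-NN interclass graph P (different-label pairs, weight
1/|Xd|), plus one shared uniform adjacency W with every entry 1/N^2 whose
Laplacian L_W turns X L_W X^T into the biased sample covariance of the view.
Quadratic forms in the graph Laplacians measure weighted pairwise squared
distances after projection: minimising Tr(H^T X L_G X^T H) compacts
same-class pairs, maximising the interclass counterpart separates classes,
and the covariance term preserves global structure, PCA-style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class PairSets:
    """Exhaustive partition of unordered sample pairs by label equality."""

    labels: np.ndarray
    intraclass: frozenset  # {(i, j) : i < j, label_i == label_j}
    interclass: frozenset  # {(i, j) : i < j, label_i != label_j}

    @property
    def n_intra(self) -> int:
        return len(self.intraclass)

    @property
    def n_inter(self) -> int:
        return len(self.interclass)


def build_pair_sets(labels: np.ndarray) -> PairSets:
    """Split all unordered index pairs into intraclass and interclass sets.

    With a single class present the interclass set is empty; this is legal
    but degenerate (the interclass graph would be all-zero), so a warning
    is emitted.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < 2:
        raise ValueError("need at least two samples")
    intra, inter = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (intra if labels[i] == labels[j] else inter).append((i, j))
    if not inter:
        warnings.warn(
            "only one class present: interclass pair set is empty",
            stacklevel=2,
        )
    return PairSets(labels=labels, intraclass=frozenset(intra), interclass=frozenset(inter))


def _knn_sets(X: np.ndarray, candidates: list[np.ndarray], k: int) -> list[set[int]]:
    """Per-sample k nearest neighbours restricted to a candidate pool.

    Euclidean distance over columns of X; ties broken by lower sample index
    (stable lexicographic sort on (distance, index)).
    """
    n = X.shape[1]
    D = cdist(X.T, X.T)
    out: list[set[int]] = []
    for i in range(n):
        pool = candidates[i]
        order = pool[np.lexsort((pool, D[i, pool]))]
        out.append(set(order[:k].tolist()))
    return out


def _pair_graph(
    X: np.ndarray,
    pairs: frozenset,
    labels: np.ndarray,
    k: int,
    same_class: bool,
    weight: float,
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if labels.size != n:
        raise ValueError("labels do not match the number of columns")
    eq = labels[:, None] == labels[None, :]
    candidates = []
    for i in range(n):
        mask = eq[i] if same_class else ~eq[i]
        idx = np.flatnonzero(mask)
        candidates.append(idx[idx != i])
    pool_sizes = [c.size for c in candidates]
    if min(pool_sizes) == 0:
        # Degenerate: some sample has no candidate neighbours at all.
        return np.zeros((n, n))
    if k < 1 or k > min(pool_sizes):
        kind = "same-class" if same_class else "opposite-class"
        raise ValueError(
            f"k={k} out of range: smallest {kind} candidate pool has "
            f"{min(pool_sizes)} samples"
        )
    neigh = _knn_sets(X, candidates, k)
    A = np.zeros((n, n))
    for i, j in pairs:
        if j in neigh[i] or i in neigh[j]:
            A[i, j] = A[j, i] = weight
    return A


def build_intraclass_graph(X: np.ndarray, pairs: PairSets, k1: int) -> np.ndarray:
    """k1-NN graph over same-label pairs, nonzero entries 1/|Xs|.

    An edge (i, j) is present iff the labels agree and i is among the k1
    nearest same-class neighbours of j or vice versa (symmetric OR rule).
    Neighbours are searched among same-class samples only.
    """
    if pairs.n_intra == 0:
        return np.zeros((pairs.labels.size,) * 2)
    return _pair_graph(
        X, pairs.intraclass, pairs.labels, k1, same_class=True,
        weight=1.0 / pairs.n_intra,
    )


def build_interclass_graph(X: np.ndarray, pairs: PairSets, k2: int) -> np.ndarray:
    """k2-NN graph over different-label pairs, nonzero entries 1/|Xd|."""
    if pairs.n_inter == 0:
        return np.zeros((pairs.labels.size,) * 2)
    return _pair_graph(
        X, pairs.interclass, pairs.labels, k2, same_class=False,
        weight=1.0 / pairs.n_inter,
    )


def laplacian(A: np.ndarray) -> np.ndarray:
    """Graph Laplacian L = D - A with D the diagonal degree matrix."""
    A = np.asarray(A, dtype=float)
    return np.diag(A.sum(axis=1)) - A


def global_structure(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform adjacency W (every entry 1/n^2) and its Laplacian L_W.

    The degree matrix is diag(1/n), so L_W = I/n - 11^T/n^2 and for any
    view matrix X (features x samples), X L_W X^T is exactly the biased
    sample covariance of the columns of X.
    """
    if n < 1:
        raise ValueError("n must be positive")
    W = np.full((n, n), 1.0 / n**2)
    L_W = np.eye(n) / n - W
    return W, L_W


@dataclass
class ViewGraphs:
    """All graph Laplacians needed by the optimizer, one set per view."""

    L_G: list[np.ndarray]
    L_P: list[np.ndarray]
    L_W: np.ndarray
    k1: int
    k2: int
    pairs: PairSets

    @classmethod
    def build(cls, dataset, k1: int, k2: int) -> "ViewGraphs":
        """Build intraclass/interclass graphs per view plus the shared L_W."""
        pairs = build_pair_sets(dataset.labels)
        L_G, L_P = [], []
        for _, X in dataset.views:
            L_G.append(laplacian(build_intraclass_graph(X, pairs, k1)))
            L_P.append(laplacian(build_interclass_graph(X, pairs, k2)))
        _, L_W = global_structure(dataset.n_samples)
        return cls(L_G=L_G, L_P=L_P, L_W=L_W, k1=k1, k2=k2, pairs=pairs)
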