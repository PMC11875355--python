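"""Adaptive similarity-graph learning.

Each row of the similarity matrix S solves a simplex-constrained quadratic
problem: minimize sum_j (d_ij s_ij + (gamma_i / alpha-scaled) s_ij^2) subject
to the row lying on the probability simplex.  Choosing the per-row trade-off
gamma_i so that exactly k neighbors receive positive weight yields a closed
form: the j-th nearest neighbor of sample i gets

    s_ij = (d_{i,(k+1)} - d_{i,(j)}) / (k d_{i,(k+1)} - sum_{m<=k} d_{i,(m)})

and all other entries are zero.  The regularization scale gamma is the mean
of the per-row gamma_i and enters the global objective as gamma ||S||_F^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SimilarityGraph:
    """A k-sparse row-stochastic similarity matrix with its regularizer scale.

    Attributes
    ----------
    S : ndarray of shape (n, n)
        Nonnegative, zero diagonal; each row sums to 1 and (for generic
        distance inputs) has exactly ``k`` positive entries.
    k : int
        Number of neighbors per row.
    gamma_i : ndarray of shape (n,)
        Per-row regularization scale (alpha/2) (k d_(k+1) - sum_{m<=k} d_(m)).
    gamma : float
        Mean of ``gamma_i``; the coefficient of ||S||_F^2 in the objective.
    alpha : float
        The graph-term weight used when forming gamma.
    """

    S: np.ndarray
    k: int
    gamma_i: np.ndarray
    gamma: float
    alpha: float


def projected_sq_distances(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between rows of XW.

    Entry (i, j) is ||W^T x_i - W^T x_j||_2^2.  With W the identity this is
    the ordinary pairwise squared distance matrix of the rows of X.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: X is {X.shape}, W is {W.shape}")
    P = X @ W
    sq = np.einsum("ij,ij->i", P, P)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (P @ P.T)
    np.maximum(D2, 0.0, out=D2)  # clip round-off negatives
    D2 = (D2 + D2.T) / 2.0
    np.fill_diagonal(D2, 0.0)
    return D2


def update_similarity(D2: np.ndarray, k: int, alpha: float = 1.0) -> SimilarityGraph:
    """Closed-form k-sparse simplex update of every row of S.

    For each sample the distances to the other n-1 points are sorted
    ascending (stable, ties broken by index); the k nearest receive the
    weights of the closed form above and all others zero.  Degenerate rows
    where the k+1 nearest distances are all equal (zero denominator) fall
    back to uniform 1/k over the k nearest.

    The printed closed form carries the graph weight alpha in both numerator
    and denominator; it cancels exactly, so S itself is alpha-free — alpha
    only scales gamma_i and gamma.
    """
    D2 = np.asarray(D2, dtype=float)
    n = D2.shape[0]
    if D2.shape != (n, n):
        raise ValueError(f"D2 must be square, got {D2.shape}")
    if not 1 <= k <= n - 2:
        raise ValueError(f"k must satisfy 1 <= k <= n-2, got k={k}, n={n}")

    # exclude self: push the diagonal past every real distance before sorting
    D_work = D2.copy()
    np.fill_diagonal(D_work, np.inf)
    order = np.argsort(D_work, axis=1, kind="stable")
    d_sorted = np.take_along_axis(D_work, order, axis=1)

    d_k1 = d_sorted[:, k]  # (k+1)-th nearest distance
    sum_k = d_sorted[:, :k].sum(axis=1)
    denom = k * d_k1 - sum_k

    S = np.zeros((n, n))
    rows = np.arange(n)[:, None]
    nn = order[:, :k]
    degenerate = denom <= np.finfo(float).tiny
    weights = np.empty((n, k))
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = (d_k1[:, None] - d_sorted[:, :k]) / denom[:, None]
    weights[degenerate] = 1.0 / k
    S[rows, nn] = weights

    gamma_i = (alpha / 2.0) * denom
    return SimilarityGraph(S=S, k=k, gamma_i=gamma_i, gamma=float(gamma_i.mean()), alpha=alpha)


def laplacian(graph: SimilarityGraph) -> np.ndarray:
    """Graph Laplacian L = D - (S + S^T)/2 of the symmetrized similarity.

    The closed-form row update yields an asymmetric S while the manifold
    quadratic form presumes symmetry; symmetrizing preserves total row-sum
    mass and keeps L symmetric positive semidefinite with zero row sums.
    """
    S_hat = (graph.S + graph.S.T) / 2.0
    deg = S_hat.sum(axis=1)
    L = np.diag(deg) - S_hat
    return L


def save_triplets(graph: SimilarityGraph, path) -> None:
    """Write S as (i, j, weight) triplets for inspection."""
    i, j = np.nonzero(graph.S)
    np.savetxt(
        path,
        np.column_stack([i, j, graph.S[i, j]]),
        fmt=["%d", "%d", "%.12g"],
        delimiter="\t",
        header="i\tj\tweight",
        comments="",
    )
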