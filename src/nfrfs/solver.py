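"""The NFRFS solver: objective, reweighting, multiplicative updates, fitting.

The optimization problem is

    min_{W>=0, H>=0, S}  ||X - XWH||_{2,p}^p
                         + alpha Tr(W^T X^T L X W)
                         + beta  (Tr(1_{dxd} W W^T) - Tr(W W^T))
                         + gamma ||S||_F^2

with rows of S on the probability simplex and an orthogonality penalty of
weight lambda applied softly inside the W update.  The residual term is
handled by iteratively reweighted least squares: a diagonal matrix U with
u_ii = (p/2) ||r_i||_2^{p-2} (eps-smoothed) turns the l2,p row norm into a
weighted Frobenius problem, after which W and H follow multiplicative
nonnegative update rules and S has the closed form of :mod:`nfrfs.graph`.
Features are ranked by the row norms ||w_i||_2 of the fitted W.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from nfrfs.data import DataMatrix
from nfrfs.graph import SimilarityGraph, laplacian, projected_sq_distances, update_similarity

logger = logging.getLogger(__name__)

VARIANTS = ("full", "base", "base_graph")


@dataclass
class SolverConfig:
    """Hyperparameters of the solver.

    Parameters
    ----------
    alpha : float
        Weight of the graph (manifold) regularizer.  >= 0.
    beta : float
        Weight of the inner-product redundancy regularizer.  >= 0.
    p : float
        Exponent of the l2,p residual norm, in (0, 2]; p = 2 recovers the
        squared Frobenius loss, smaller p down-weights outlier samples.
    k : int
        Neighbors per row of the adaptive graph.
    lam : float
        Soft orthogonality penalty on W.  The update rules push W toward
        having one dominant entry per column; 1e4 discourages collinear
        columns without dominating the data terms.
    l : int
        Number of latent components (columns of W).  Best kept of the order
        of the expected number of clusters; much larger values let individual
        high-variance noise features claim components of their own.
    max_iter : int
        Maximum alternating iterations.
    tol : float
        Relative objective-change stopping tolerance.
    seed : int
        Seed for the strictly positive Uniform(0.1, 1) initialization of W, H.
    eps : float
        Smoothing for the residual reweighting and update denominators.
    variant : {"full", "base", "base_graph"}
        Ablation switch: "base" drops the graph terms entirely, "base_graph"
        keeps a fixed initial graph, "full" relearns S each iteration.
    """

    alpha: float = 1.0
    beta: float = 1.0
    p: float = 0.5
    k: int = 5
    lam: float = 1e4
    l: int = 5
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0
    eps: float = 1e-12
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.lam < 0:
            raise ValueError("alpha, beta and lam must be >= 0")
        if not 0 < self.p <= 2:
            raise ValueError(f"p must lie in (0, 2], got {self.p}")
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")


@dataclass
class SolverState:
    """Everything the alternating loop maintains, plus its history."""

    W: np.ndarray
    H: np.ndarray
    graph: SimilarityGraph | None
    U_diag: np.ndarray
    objective_history: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


@dataclass
class FeatureRanking:
    """Per-feature importance scores ||w_i||_2 and the induced selection."""

    scores: np.ndarray
    order: np.ndarray
    selected: np.ndarray

    def to_frame(self, feature_ids=None):
        import pandas as pd

        d = self.scores.shape[0]
        ids = feature_ids if feature_ids is not None else [f"f{i}" for i in range(d)]
        rank = np.empty(d, dtype=int)
        rank[self.order] = np.arange(d)
        return pd.DataFrame(
            {
                "feature_id": ids,
                "score": self.scores,
                "rank": rank,
                "selected": np.isin(np.arange(d), self.selected),
            }
        )


def l2p_norm_p(M: np.ndarray, p: float) -> float:
    """``||M||_{2,p}^p``: the sum over rows of the p-th power of row 2-norms."""
    if not 0 < p <= 2:
        raise ValueError(f"p must lie in (0, 2], got {p}")
    row_norms = np.linalg.norm(np.atleast_2d(M), axis=1)
    return float(np.sum(row_norms**p))


def residual_weights(
    X: np.ndarray, W: np.ndarray, H: np.ndarray, p: float, eps: float = 1e-12
) -> np.ndarray:
    """Diagonal of the IRLS reweighting matrix U.

    u_ii = (p/2) (||r_i||_2^2 + eps)^{(p-2)/2} with r_i the i-th row of
    X - XWH; eps guards the singularity at vanishing residual for p < 2.
    At p = 2 the exponent is zero and every weight is exactly 1.
    """
    R = X - X @ W @ H
    sq = np.einsum("ij,ij->i", R, R)
    return (p / 2.0) * (sq + eps) ** ((p - 2.0) / 2.0)


def _inner_product_penalty(W: np.ndarray) -> float:
    # Tr(1 W W^T) - Tr(W W^T) = ||sum of rows||^2 - ||W||_F^2
    row_sum = W.sum(axis=0)
    return float(row_sum @ row_sum - np.sum(W * W))


def objective(X: np.ndarray, state: SolverState, config: SolverConfig) -> float:
    """Value of the full objective at the current state."""
    return sum(objective_terms(X, state, config).values())


def objective_terms(X: np.ndarray, state: SolverState, config: SolverConfig) -> dict:
    """Term-wise breakdown of the objective, for logging and diagnostics."""
    terms = {"residual": l2p_norm_p(X - X @ state.W @ state.H, config.p)}
    if config.variant != "base" and state.graph is not None:
        L = laplacian(state.graph)
        XW = X @ state.W
        terms["graph"] = config.alpha * float(np.sum(XW * (L @ XW)))
    terms["redundancy"] = config.beta * _inner_product_penalty(state.W)
    if config.variant == "full" and state.graph is not None:
        terms["graph_scale"] = state.graph.gamma * float(np.sum(state.graph.S**2))
    return terms


def _w_update_factors(X, W, H, u, graph, config):
    """Numerator and denominator of the multiplicative W rule."""
    XHt = X @ H.T
    num = X.T @ (u[:, None] * XHt) + (config.beta + config.lam) * W
    XW = X @ W
    HHt = H @ H.T
    den = X.T @ (u[:, None] * (XW @ HHt))
    den += config.beta * W @ (W.T @ W)
    den += config.lam * np.broadcast_to(W.sum(axis=0), W.shape)  # 1_{dxd} W
    if graph is not None and config.alpha > 0:
        S_hat = (graph.S + graph.S.T) / 2.0
        deg = S_hat.sum(axis=1)
        num += config.alpha * (X.T @ (S_hat @ XW))
        den = den + config.alpha * (X.T @ (deg[:, None] * XW))
    return num, den


def update_W(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    u: np.ndarray,
    graph: SimilarityGraph | None,
    config: SolverConfig,
) -> np.ndarray:
    """One multiplicative update of the feature selection matrix W.

    W <- W * [X^T U X H^T + alpha X^T S_hat X W + beta W + lam W]
           / [X^T U X W H H^T + alpha X^T D X W + beta W W^T W + lam 1 W]

    elementwise; nonnegativity is preserved because every factor is
    nonnegative for nonnegative inputs.
    """
    num, den = _w_update_factors(X, W, H, u, graph, config)
    return W * num / (den + config.eps)


def update_H(
    X: np.ndarray, W: np.ndarray, H: np.ndarray, u: np.ndarray, config: SolverConfig
) -> np.ndarray:
    """One multiplicative update of the reconstruction matrix H.

    H <- H * [W^T X^T U X] / [W^T X^T U X W H] elementwise; this is the
    multiplicative rule for the weighted least-squares subproblem in H.
    """
    XW = X @ W
    num = XW.T @ (u[:, None] * X)
    den = XW.T @ (u[:, None] * XW) @ H
    return H * num / (den + config.eps)


def kkt_residual(
    X: np.ndarray, state: SolverState, config: SolverConfig, scale: str = "objective"
) -> float:
    """Scaled complementarity residual ``max|W * (den - num)|`` of the W rule.

    Zero at an exact fixed point of the multiplicative update (the KKT
    stationarity-with-complementarity condition of the nonnegativity
    constraint); small values certify numerical convergence in W.

    Each elementwise product W_ij * (den - num)_ij carries the units of the
    objective (W times its gradient), so the default normalization divides
    by the current objective value, giving a dimensionless residual that is
    invariant to rescaling the whole objective.  ``scale="max_product"``
    instead normalizes by max|W * den|, the largest balanced term of the
    update; it is invariant to rescaling W and typically stricter.
    """
    u = residual_weights(X, state.W, state.H, config.p, config.eps)
    num, den = _w_update_factors(X, state.W, state.H, u, state.graph, config)
    raw = float(np.max(np.abs(state.W * (den - num))))
    if scale == "objective":
        denom = objective(X, state, config)
    elif scale == "max_product":
        denom = float(np.max(np.abs(state.W * den)))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if denom == 0:
        return 0.0
    return raw / denom


def fit(data: DataMatrix, config: SolverConfig) -> SolverState:
    """Run the alternating NFRFS optimization on a nonnegative data matrix.

    Per iteration: recompute the IRLS weights U, update W, update H, then
    (for the full variant) recompute projected distances and relearn S and
    gamma; the objective value is recorded after each sweep and the loop
    stops at ``max_iter`` or when its relative change drops below ``tol``.
    """
    X = data.X
    if X.min() < 0:
        raise ValueError(
            "fit requires a nonnegative X (min-max normalize first); "
            f"found minimum {X.min():.3g}"
        )
    n, d = X.shape
    if config.l > d:
        raise ValueError(f"l={config.l} exceeds the number of features d={d}")
    if config.variant != "base" and not 1 <= config.k <= n - 2:
        raise ValueError(f"k={config.k} out of range for n={n} samples")

    rng = np.random.default_rng(config.seed)
    W = rng.uniform(0.1, 1.0, size=(d, config.l))
    H = rng.uniform(0.1, 1.0, size=(config.l, d))

    graph = None
    if config.variant != "base":
        graph = update_similarity(projected_sq_distances(X, W), config.k, config.alpha)

    state = SolverState(W=W, H=H, graph=graph, U_diag=np.ones(n))
    prev_obj = None
    for t in range(config.max_iter):
        u = residual_weights(X, state.W, state.H, config.p, config.eps)
        state.U_diag = u
        state.W = update_W(X, state.W, state.H, u, state.graph, config)
        state.H = update_H(X, state.W, state.H, u, config)
        if config.variant == "full":
            D2 = projected_sq_distances(X, state.W)
            state.graph = update_similarity(D2, config.k, config.alpha)
        obj = objective(X, state, config)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite objective at iteration {t}: "
                f"{objective_terms(X, state, config)}"
            )
        state.objective_history.append(obj)
        state.iterations_run = t + 1
        if t % 10 == 0:
            logger.info("iter %d: %s", t, objective_terms(X, state, config))
        if prev_obj is not None and abs(prev_obj - obj) < config.tol * abs(prev_obj):
            state.converged = True
            break
        prev_obj = obj
    return state


def rank_features(state: SolverState, m: int) -> FeatureRanking:
    """Rank features by the row norms of W and select the top m.

    Ordering is by descending score with ascending-index tie-break, so it is
    deterministic and invariant to positive rescaling of W.
    """
    scores = np.linalg.norm(state.W, axis=1)
    d = scores.shape[0]
    if not 1 <= m <= d:
        raise ValueError(f"m must lie in [1, {d}], got {m}")
    order = np.lexsort((np.arange(d), -scores))
    return FeatureRanking(scores=scores, order=order, selected=order[:m])
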