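"""Clustering-based evaluation protocol.

Feature subsets are scored by clustering the selected columns with K-means
(repeated with distinct initializations, 20 times by default) and comparing
the partition against the true class labels by two indices:

* ACC — the fraction of samples correctly labeled after optimally mapping
  predicted clusters to true classes (maximum bipartite matching on the
  contingency table);
* NMI — mutual information normalized by the geometric mean of the two
  partition entropies: 1 for identical partitions, 0 for independent ones.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from nfrfs.data import DataMatrix
from nfrfs.solver import SolverConfig, fit, rank_features

logger = logging.getLogger(__name__)

DEFAULT_REG_GRID = (1e-6, 1e-4, 1e-2, 1.0, 1e2, 1e4, 1e6)
DEFAULT_P_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)
DEFAULT_FEATURE_COUNTS = tuple(range(20, 201, 20))


@dataclass
class ClusteringScore:
    """Best / mean / std of ACC and NMI over repeated K-means runs."""

    acc_best: float
    acc_mean: float
    acc_std: float
    nmi_best: float
    nmi_mean: float
    nmi_std: float
    n_repeats: int
    m_features: int
    config_echo: SolverConfig | None = None

    def to_dict(self) -> dict:
        return {
            "acc_best": self.acc_best,
            "acc_mean": self.acc_mean,
            "acc_std": self.acc_std,
            "nmi_best": self.nmi_best,
            "nmi_mean": self.nmi_mean,
            "nmi_std": self.nmi_std,
            "n_repeats": self.n_repeats,
            "m_features": self.m_features,
        }


def clustering_accuracy(true_labels, pred_labels) -> float:
    """Hungarian-matched clustering accuracy in [0, 1].

    Maximizes label agreement over all cluster-to-class assignments via
    optimal bipartite matching on the contingency table; equal to the
    brute-force maximum over cluster permutations.
    """
    true_labels = np.asarray(true_labels).ravel()
    pred_labels = np.asarray(pred_labels).ravel()
    if true_labels.shape != pred_labels.shape:
        raise ValueError(
            f"label length mismatch: {true_labels.shape[0]} vs {pred_labels.shape[0]}"
        )
    C = contingency_matrix(true_labels, pred_labels)
    row, col = linear_sum_assignment(-C)
    return float(C[row, col].sum() / true_labels.size)


def nmi(true_labels, pred_labels) -> float:
    """Normalized mutual information with geometric-mean normalization.

    Returns 0 (with a warning) when either partition has zero entropy, where
    the normalization is undefined.
    """
    true_labels = np.asarray(true_labels).ravel()
    pred_labels = np.asarray(pred_labels).ravel()
    if true_labels.shape != pred_labels.shape:
        raise ValueError(
            f"label length mismatch: {true_labels.shape[0]} vs {pred_labels.shape[0]}"
        )
    if np.unique(true_labels).size < 2 or np.unique(pred_labels).size < 2:
        warnings.warn("single-cluster partition has zero entropy; NMI defined as 0")
        return 0.0
    return float(
        normalized_mutual_info_score(true_labels, pred_labels, average_method="geometric")
    )


def _acc_bruteforce(true_labels, pred_labels) -> float:
    """Exhaustive-permutation ACC; test oracle, exponential in cluster count."""
    true_labels = np.asarray(true_labels).ravel()
    pred_labels = np.asarray(pred_labels).ravel()
    t_vals = np.unique(true_labels)
    p_vals = np.unique(pred_labels)
    big, small, swap = (
        (t_vals, p_vals, False) if t_vals.size >= p_vals.size else (p_vals, t_vals, True)
    )
    best = 0
    for perm in itertools.permutations(big, small.size):
        mapping = dict(zip(small, perm))
        if swap:
            agree = sum(mapping[t] == p for t, p in zip(true_labels, pred_labels))
        else:
            agree = sum(t == mapping[p] for t, p in zip(true_labels, pred_labels))
        best = max(best, agree)
    return best / true_labels.size


def kmeans_protocol(
    X_selected: np.ndarray,
    true_labels,
    c: int,
    n_repeats: int = 20,
    seed: int = 0,
    m_features: int | None = None,
    config_echo: SolverConfig | None = None,
) -> ClusteringScore:
    """Cluster the selected columns n_repeats times and summarize ACC/NMI.

    Each repeat runs K-means with ``c`` clusters from one fresh seeded
    initialization; the summary reports the best and the mean +/- population
    std across repeats.
    """
    X_selected = np.asarray(X_selected, dtype=float)
    true_labels = np.asarray(true_labels).ravel()
    if c > X_selected.shape[0]:
        raise ValueError(f"c={c} exceeds the number of samples {X_selected.shape[0]}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    accs, nmis = [], []
    for rs in child_seeds:
        km = KMeans(n_clusters=c, n_init=1, random_state=int(rs))
        pred = km.fit_predict(X_selected)
        accs.append(clustering_accuracy(true_labels, pred))
        nmis.append(nmi(true_labels, pred))
    accs = np.asarray(accs)
    nmis = np.asarray(nmis)
    return ClusteringScore(
        acc_best=float(accs.max()),
        acc_mean=float(accs.mean()),
        acc_std=float(accs.std()),
        nmi_best=float(nmis.max()),
        nmi_mean=float(nmis.mean()),
        nmi_std=float(nmis.std()),
        n_repeats=n_repeats,
        m_features=m_features if m_features is not None else X_selected.shape[1],
        config_echo=config_echo,
    )


def evaluate_selection(
    data: DataMatrix,
    selected: np.ndarray,
    n_repeats: int = 20,
    seed: int = 0,
    config_echo: SolverConfig | None = None,
) -> ClusteringScore:
    """Run the K-means protocol on a column subset of a labeled DataMatrix."""
    if data.labels is None:
        raise ValueError("evaluation requires labels on the DataMatrix")
    return kmeans_protocol(
        data.X[:, selected],
        data.labels,
        c=data.n_classes,
        n_repeats=n_repeats,
        seed=seed,
        m_features=len(selected),
        config_echo=config_echo,
    )


def grid_search(
    data: DataMatrix,
    alphas=DEFAULT_REG_GRID,
    betas=DEFAULT_REG_GRID,
    ps=DEFAULT_P_GRID,
    feature_counts=DEFAULT_FEATURE_COUNTS,
    base_config: SolverConfig | None = None,
    n_repeats: int = 20,
    seed: int = 0,
    existing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sweep (alpha, beta, p) x feature counts and score every cell.

    One solver fit per (alpha, beta, p); the resulting ranking is evaluated
    by the K-means protocol at every feature count, yielding a long-format
    table with one row per grid cell.  A previously emitted table may be
    passed as ``existing`` to resume a partial sweep; solver failures are
    logged per-cell and skipped rather than aborting the sweep.

    The defaults are the protocol grids: regularization weights
    {1e-6, ..., 1e6} (7 points each), p in {0.01, 0.05, 0.1, 0.5, 1} and
    feature counts 20..200 in steps of 20.
    """
    if data.labels is None:
        raise ValueError("grid_search requires labels for evaluation")
    base = base_config if base_config is not None else SolverConfig(seed=seed)
    done = set()
    rows: list[dict] = []
    if existing is not None and len(existing):
        rows = existing.to_dict("records")
        done = {(r["alpha"], r["beta"], r["p"], r["m"]) for r in rows}
    feature_counts = [m for m in feature_counts if m <= data.d]

    for alpha, beta, p in itertools.product(alphas, betas, ps):
        todo = [m for m in feature_counts if (alpha, beta, p, m) not in done]
        if not todo:
            continue
        cfg = dc_replace(base, alpha=alpha, beta=beta, p=p, seed=seed)
        try:
            state = fit(data, cfg)
        except Exception as exc:  # noqa: BLE001 — isolate per-cell failures
            logger.warning("fit failed at alpha=%g beta=%g p=%g: %s", alpha, beta, p, exc)
            continue
        for m in todo:
            ranking = rank_features(state, m)
            score = evaluate_selection(data, ranking.selected, n_repeats, seed, cfg)
            rows.append(
                {"alpha": alpha, "beta": beta, "p": p, "m": m, "seed": seed, **score.to_dict()}
            )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["alpha", "beta", "p", "m"]).reset_index(drop=True)
    return table


def best_result(table: pd.DataFrame, metric: str = "acc_mean") -> pd.Series:
    """The argmax row of a grid-search table for the given metric column."""
    return table.loc[table[metric].idxmax()]


def ablation_run(
    data: DataMatrix,
    config: SolverConfig,
    feature_count: int,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare the base / base_graph / full variants under shared seeds.

    base keeps only the reconstruction and redundancy terms; base_graph adds
    the manifold term on a fixed initial graph; full relearns the graph
    adaptively.  Returns one row per variant with ACC and NMI summaries.
    """
    rows = []
    for variant in ("base", "base_graph", "full"):
        cfg = dc_replace(config, variant=variant, seed=seed)
        state = fit(data, cfg)
        ranking = rank_features(state, feature_count)
        score = evaluate_selection(data, ranking.selected, n_repeats, seed, cfg)
        rows.append(
            {
                "variant": variant,
                "acc": score.acc_mean,
                "nmi": score.nmi_mean,
                "acc_best": score.acc_best,
                "nmi_best": score.nmi_best,
            }
        )
    return pd.DataFrame(rows)
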