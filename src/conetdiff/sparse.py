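"""Conditional-independence sparsification of co-abundance networks.

CLR-transformed abundances are fed to Meinshausen–Bühlmann neighborhood
selection (per-node lasso, OR-rule symmetrization) with the regularization
level chosen by StARS stability selection. The resulting graph is
intersected with the SparCC-significant edge set so that retained edges are
supported both marginally (SparCC) and conditionally (graphical model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .sparcc import fractions_from_counts, _counts_matrix


@dataclass
class SparseGraph:
    """Undirected graph with StARS metadata."""

    nodes: list[str]
    adjacency: np.ndarray  # binary, symmetric, zero diagonal
    lambda_star: float | None = None
    selection_frequency: np.ndarray | None = None  # at lambda_star
    lambda_path: np.ndarray | None = None
    instability: np.ndarray | None = None  # monotonized, per lambda
    no_lambda_met_criterion: bool = False
    extras: dict = field(default_factory=dict)


def clr_transform(fractions: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform: log f_i − mean_k log f_k per sample."""
    f = np.asarray(fractions, dtype=float)
    if (f <= 0).any():
        raise ValueError("CLR requires strictly positive fractions")
    logf = np.log(f)
    return logf - logf.mean(axis=1, keepdims=True)


def clr_from_counts(counts) -> np.ndarray:
    """CLR of Dirichlet-posterior-mean fractions (samples × features)."""
    return clr_transform(fractions_from_counts(counts))


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def lambda_max(clr: np.ndarray) -> float:
    """Smallest penalty giving an empty graph: max |<x_j, y_i>|/n over pairs
    (standardized predictors, centered responses; sklearn alpha scale)."""
    z = _standardize(np.asarray(clr, float))
    n = z.shape[0]
    grad = np.abs(z.T @ z) / n
    np.fill_diagonal(grad, 0.0)
    return float(grad.max())


def default_lambda_path(clr: np.ndarray, n_lambda: int = 20) -> np.ndarray:
    """Log-spaced path from λ_max down to 0.01·λ_max (descending)."""
    lmax = lambda_max(clr)
    return np.geomspace(lmax, 0.01 * lmax, n_lambda)


def _neighborhood_adjacency(z: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Adjacency per λ via per-node lasso paths, OR-symmetrized.

    ``z`` is standardized (samples × features); returns (len(lams), p, p).
    """
    n, p = z.shape
    adj = np.zeros((len(lams), p, p), dtype=bool)
    for i in range(p):
        x = np.delete(z, i, axis=1)
        y = z[:, i]
        _, coefs, _ = lasso_path(x, y, alphas=lams)
        others = [j for j in range(p) if j != i]
        nz = coefs != 0  # (p-1, n_lambda)
        for k in range(len(lams)):
            sel = nz[:, k]
            for idx, j in enumerate(others):
                if sel[idx]:
                    adj[k, i, j] = adj[k, j, i] = True  # OR rule
    return adj


def mb_neighborhood(clr: np.ndarray, lam: float, nodes=None) -> SparseGraph:
    """Meinshausen–Bühlmann neighborhood selection at a single penalty.

    Each node's CLR column is lasso-regressed on all others (standardized
    predictors); an edge is present if either direction selects it.
    """
    clr = np.asarray(clr, dtype=float)
    if not np.isfinite(clr).all():
        raise ValueError("non-finite values in CLR matrix")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    z = _standardize(clr)
    adj = _neighborhood_adjacency(z, np.array([max(lam, 1e-12)]))[0]
    p = clr.shape[1]
    names = list(nodes) if nodes is not None else [f"F{i:03d}" for i in range(p)]
    return SparseGraph(nodes=names, adjacency=adj.astype(np.int8), lambda_star=lam)


def stars_select(
    clr: np.ndarray,
    lambda_path: np.ndarray | None = None,
    n_subsamples: int = 50,
    subsample_size: int | None = None,
    beta: float = 0.05,
    seed=None,
    nodes=None,
) -> SparseGraph:
    """StARS: pick the densest penalty whose edge instability stays ≤ β.

    Edge selection frequencies θ̂ are estimated over subsamples of size
    min(⌊10√n⌋, 0.8n); instability D(λ) = mean over edges of 2θ̂(1−θ̂),
    monotonized along increasing density. λ* is the smallest λ with
    monotonized instability ≤ β; the returned graph is the full-data
    neighborhood graph at λ*. If no λ qualifies, the sparsest graph is
    returned with ``no_lambda_met_criterion`` set.
    """
    clr = np.asarray(clr, dtype=float)
    n, p = clr.shape
    if n < 20:
        raise ValueError("StARS needs at least 20 samples")
    if lambda_path is None:
        lambda_path = default_lambda_path(clr)
    lams = np.sort(np.asarray(lambda_path, float))[::-1]  # sparse -> dense
    if subsample_size is None:
        subsample_size = min(int(np.floor(10 * np.sqrt(n))), int(0.8 * n))
    rng = np.random.default_rng(seed)

    freq = np.zeros((len(lams), p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        z = _standardize(clr[idx])
        freq += _neighborhood_adjacency(z, lams)
    theta = freq / n_subsamples

    iu = np.triu_indices(p, k=1)
    xi = 2.0 * theta * (1.0 - theta)
    d = xi[:, iu[0], iu[1]].mean(axis=1)
    d_mono = np.maximum.accumulate(d)  # non-decreasing along increasing density
    ok = np.flatnonzero(d_mono <= beta)
    if ok.size:
        k_star = ok[-1]  # densest (smallest λ) allowed
        failed = False
    else:
        k_star = 0
        failed = True
    lam_star = float(lams[k_star])
    graph = mb_neighborhood(clr, lam_star, nodes=nodes)
    graph.selection_frequency = theta[k_star]
    graph.lambda_path = lams
    graph.instability = d_mono
    graph.no_lambda_met_criterion = failed
    return graph


def sparse_graph_from_counts(counts, seed=None, **kwargs) -> SparseGraph:
    """StARS-selected neighborhood graph straight from a count table."""
    mat, features = _counts_matrix(counts)
    clr = clr_transform(fractions_from_counts(mat.T))
    return stars_select(clr, seed=seed, nodes=features, **kwargs)


def intersect_edges(sparcc_edges: pd.DataFrame, graph: SparseGraph) -> pd.DataFrame:
    """Final co-abundance set: SparCC q < 0.05 AND present in the sparse graph.

    Effect size and sign come from the SparCC ρ; the graph contributes only
    topology (plus each edge's selection frequency).
    """
    name_to_idx = {f: i for i, f in enumerate(graph.nodes)}
    unknown = set(sparcc_edges["feature_i"]) | set(sparcc_edges["feature_j"])
    unknown -= set(graph.nodes)
    if unknown:
        raise ValueError(f"features absent from graph namespace: {sorted(unknown)}")
    sig = sparcc_edges[sparcc_edges["q"] < 0.05]
    keep, freqs = [], []
    for row in sig.itertuples():
        i, j = name_to_idx[row.feature_i], name_to_idx[row.feature_j]
        if graph.adjacency[i, j]:
            keep.append(row.Index)
            freqs.append(
                float(graph.selection_frequency[i, j])
                if graph.selection_frequency is not None
                else np.nan
            )
    out = sparcc_edges.loc[keep].copy()
    out["selection_frequency"] = freqs
    return out.reset_index(drop=True)
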