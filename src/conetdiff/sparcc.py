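"""SparCC basis-correlation inference with permutation p-values and FDR.

Relative abundances are compositional: fractions sum to 1 per sample, which
induces spurious negative correlation. SparCC estimates the correlations of
the unobserved absolute ("basis") abundances from the matrix of log-ratio
variances t_ij = var(log(f_i/f_j)) under a sparsity assumption: approximating
Σ_j t_ij by (p-2)ω_i² + Σ_k ω_k² yields a linear system for the basis
variances ω², from which ρ_ij = (ω_i² + ω_j² − t_ij)/(2 ω_i ω_j). Strongly
correlated pairs violate the approximation and are iteratively excluded from
the row sums. Estimates are averaged over Dirichlet-resampled fractions, and
per-cohort edge significance uses a per-feature shuffling permutation test
with a plug-in permutation FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import perm_pvalues, plugin_fdr, spawn_seeds
from .tables import CountTable

_EPS = np.finfo(float).eps


@dataclass
class SparccBasis:
    """Log-ratio variances, basis variances and basis correlations."""

    t: np.ndarray  # p × p log-ratio variance matrix
    omega2: np.ndarray  # basis variances
    rho: np.ndarray  # basis correlations, clamped to [-1, 1]
    degenerate: np.ndarray  # features whose solved variance was non-positive
    n_excluded: int = 0


def _counts_matrix(counts) -> tuple[np.ndarray, list[str]]:
    """Return (samples × features) float matrix and feature names."""
    if isinstance(counts, CountTable):
        return counts.data.to_numpy(dtype=float).T, list(counts.data.index)
    if isinstance(counts, pd.DataFrame):  # features × samples, as on disk
        return counts.to_numpy(dtype=float).T, list(counts.index)
    arr = np.asarray(counts, dtype=float)
    return arr.T, [f"F{i:03d}" for i in range(arr.shape[0])]


def fractions_from_counts(counts) -> np.ndarray:
    """Dirichlet-posterior-mean fractions (c+1)/(depth+p), strictly positive.

    The symmetric +1 prior handles zero counts; rows (samples) sum to 1.
    """
    mat, _ = _counts_matrix(counts)
    depth = mat.sum(axis=1, keepdims=True)
    return (mat + 1.0) / (depth + mat.shape[1])


def _dirichlet_fractions(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw of fractions per sample from Dirichlet(counts + 1)."""
    g = rng.standard_gamma(mat + 1.0)
    return g / g.sum(axis=1, keepdims=True)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = sample variance (n−1 denominator) of log(f_i) − log(f_j).

    Computed via the covariance of log fractions:
    t_ij = var(log f_i) + var(log f_j) − 2 cov(log f_i, log f_j).
    """
    f = np.asarray(fractions, dtype=float)
    if (f <= 0).any():
        raise ValueError("fractions must be strictly positive (smooth zeros first)")
    if f.shape[0] < 2:
        raise ValueError("need at least 2 samples for a variance")
    logf = np.log(f)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.maximum((t + t.T) / 2.0, 0.0)
    np.fill_diagonal(t, 0.0)
    return t


def basis_correlations(
    t: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> SparccBasis:
    """Solve the SparCC linear approximation for basis variances/correlations.

    After each solve, the most strongly correlated remaining pair with
    |ρ| > ``exclusion_threshold`` is excluded from the row sums and the
    system re-solved, up to ``max_exclusions`` rounds. Non-positive solved
    variances are floored at machine epsilon and flagged; if more than p/2
    features are flagged the input is considered degenerate.
    """
    t = np.asarray(t, dtype=float)
    p = t.shape[0]
    if p < 4:
        raise ValueError("SparCC needs at least 4 features (system under-determined)")
    excluded = np.zeros((p, p), dtype=bool)
    rho = np.zeros((p, p))
    omega2 = np.zeros(p)
    degenerate = np.zeros(p, dtype=bool)
    n_excluded = 0
    for round_ in range(max_exclusions + 1):
        adj = ~excluded
        np.fill_diagonal(adj, False)
        deg = adj.sum(axis=1).astype(float)
        m = np.diag(deg) + adj.astype(float)
        rowsum = np.where(adj, t, 0.0).sum(axis=1)
        omega2 = np.linalg.solve(m, rowsum)
        degenerate = omega2 <= 0
        if degenerate.sum() > p / 2:
            raise ValueError(
                f"{int(degenerate.sum())} of {p} basis variances non-positive: "
                "degenerate input"
            )
        omega2 = np.where(degenerate, _EPS, omega2)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        if round_ == max_exclusions:
            break
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        cand[excluded] = 0.0
        # excluding below 3 remaining partners would make the system singular
        starved = deg <= 3
        cand[starved, :] = 0.0
        cand[:, starved] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        n_excluded += 1
    return SparccBasis(
        t=t, omega2=omega2, rho=rho, degenerate=degenerate, n_excluded=n_excluded
    )


def sparcc(
    counts,
    n_inner: int = 20,
    seed=None,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> np.ndarray:
    """SparCC correlation matrix, averaged over Dirichlet-resampled fractions.

    With ``n_inner == 1`` the single estimate uses the posterior-mean
    fractions (no resampling), which makes the reduction to
    :func:`basis_correlations` exact and deterministic.
    """
    mat, _ = _counts_matrix(counts)
    if n_inner == 1:
        frac = fractions_from_counts(mat.T)
        return basis_correlations(
            log_ratio_variances(frac), exclusion_threshold, max_exclusions
        ).rho
    rng = np.random.default_rng(seed)
    acc = np.zeros((mat.shape[1], mat.shape[1]))
    for _ in range(n_inner):
        frac = _dirichlet_fractions(mat, rng)
        acc += basis_correlations(
            log_ratio_variances(frac), exclusion_threshold, max_exclusions
        ).rho
    rho = acc / n_inner
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _shuffle_features(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each feature's values across samples."""
    out = np.empty_like(mat)
    n = mat.shape[0]
    for j in range(mat.shape[1]):
        out[:, j] = mat[rng.permutation(n), j]
    return out


def permutation_edge_test(
    counts,
    n_perm: int = 100,
    seed=None,
    n_inner: int = 20,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Per-edge SparCC estimates with permutation p-values and plug-in FDR.

    Each permutation shuffles every feature's values across samples
    independently, destroying all correlation while preserving marginals.
    p_perm = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_perm + 1); q is the
    ratio-of-expected-discoveries FDR at each edge's own |ρ|, monotonized.

    Returns a tidy frame with columns feature_i, feature_j, rho, p_perm, q, n
    (pairs stored with i < j in feature order).
    """
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} gives coarse FDR resolution", stacklevel=2)
    mat, features = _counts_matrix(counts)
    n, p = mat.shape
    seeds = spawn_seeds(seed, n_perm + 1)
    rho_obs = sparcc(mat.T, n_inner=n_inner, seed=seeds[0])
    iu = np.triu_indices(p, k=1)
    obs = np.abs(rho_obs[iu])

    rng = np.random.default_rng(seeds[0] ^ 0x5EED)
    perm = np.empty((n_perm, obs.size))
    for b in range(n_perm):
        shuffled = _shuffle_features(mat, rng)
        rho_b = sparcc(shuffled.T, n_inner=n_inner, seed=seeds[b + 1])
        perm[b] = np.abs(rho_b[iu])

    pvals = perm_pvalues(obs, perm)
    qvals = plugin_fdr(obs, perm)
    out = pd.DataFrame(
        {
            "feature_i": [features[i] for i in iu[0]],
            "feature_j": [features[j] for j in iu[1]],
            "rho": rho_obs[iu],
            "p_perm": pvals,
            "q": qvals,
            "n": n,
        }
    )
    if cohort is not None:
        out.insert(2, "cohort", cohort)
    return out
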