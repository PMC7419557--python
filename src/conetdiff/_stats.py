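"""Shared permutation-test machinery.

Plug-in (ratio-of-expected-discoveries) permutation FDR: at a threshold t the
estimated FDR is the mean number of permuted statistics passing t divided by
the number of observed statistics passing t, monotonized so that q never
decreases as the statistic weakens.
"""

from __future__ import annotations

import warnings

import numpy as np

MIN_PERMUTATIONS = 20


def perm_pvalues(obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Per-statistic permutation p-values with the (1+k)/(B+1) floor.

    Parameters
    ----------
    obs : (m,) observed statistics, larger = more significant.
    perm : (B, m) permuted statistics, column-matched to ``obs``.
    """
    obs = np.asarray(obs, dtype=float)
    perm = np.asarray(perm, dtype=float)
    n_perm = perm.shape[0]
    exceed = (perm >= obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)


def plugin_fdr(obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Plug-in permutation FDR (q-value) per observed statistic.

    Larger statistics are treated as more significant; each observed value is
    its own threshold. q is monotone non-increasing in the statistic. When no
    observed statistic passes a threshold the FDR of the empty discovery set
    is 0 by convention (cannot occur per-edge since each edge passes its own
    threshold).
    """
    obs = np.asarray(obs, dtype=float)
    perm = np.asarray(perm, dtype=float)
    n_perm = perm.shape[0]
    if n_perm < MIN_PERMUTATIONS:
        warnings.warn(
            f"only {n_perm} permutations: FDR resolution is coarse",
            stacklevel=2,
        )
    m = obs.size
    order = np.argsort(-obs, kind="stable")  # descending significance
    sorted_obs = obs[order]
    pooled = np.sort(perm.ravel())
    # permuted discovery count at each observed threshold (>= t)
    perm_count = pooled.size - np.searchsorted(pooled, sorted_obs, side="left")
    obs_count = np.arange(1, m + 1, dtype=float)
    raw = (perm_count / n_perm) / obs_count
    # monotonize: q at a strong threshold <= q at any weaker one
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def plugin_fdr_pvalues(p_obs: np.ndarray, p_perm: np.ndarray) -> np.ndarray:
    """Plug-in FDR when the statistic is a p-value (smaller = significant)."""
    return plugin_fdr(-np.asarray(p_obs, float), -np.asarray(p_perm, float))


def fdr_threshold(p_obs: np.ndarray, p_perm: np.ndarray, alpha: float = 0.05) -> float:
    """Operational p-value threshold of the plug-in FDR selection.

    The largest threshold t at which the estimated FDR — mean permuted
    discovery count at t over observed discovery count at t — stays ≤ alpha.
    Defined on the full FDR curve, so it lies in the gap between the last
    selected observed p-value and the point where permuted discoveries make
    the ratio exceed alpha (this is the threshold the selection effectively
    applies, and the one to reuse inside permutations).
    """
    p_obs = np.sort(np.asarray(p_obs, float))
    pooled = np.sort(np.asarray(p_perm, float).ravel())
    n_perm = np.asarray(p_perm).shape[0]
    grid = np.unique(np.concatenate([p_obs, pooled]))
    obs_count = np.searchsorted(p_obs, grid, side="right")
    perm_count = np.searchsorted(pooled, grid, side="right") / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_count > 0, perm_count / np.maximum(obs_count, 1), np.inf)
    ok = np.flatnonzero((fdr <= alpha) & (obs_count > 0))
    if ok.size == 0:
        return 0.0
    k = ok[-1]
    # extend t to just below the next grid point (the FDR is flat in between)
    return float(grid[k + 1]) * (1 - 1e-12) if k + 1 < grid.size else float(grid[k])


def spawn_seeds(seed, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
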