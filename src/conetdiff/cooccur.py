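"""Presence/absence co-occurrence and co-exclusion networks.

Each feature's detection (abundance > 0) is treated as a binary trait.
Pairwise association is tested with Pearson's chi-squared statistic (no
continuity correction); the effect size is the odds ratio of the 2×2
presence table (Haldane–Anscombe +0.5 on all cells when any cell is zero).
OR > 1 is called co-occurrence, OR < 1 co-exclusion. Significance uses the
same per-feature shuffling permutation FDR as the co-abundance network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import perm_pvalues, plugin_fdr, spawn_seeds
from .tables import AbundanceTable


@dataclass
class CooccurrenceEdge:
    """One feature pair's 2×2 presence table and test results."""

    feature_i: str
    feature_j: str
    a: int  # both present
    b: int  # i only
    c: int  # j only
    d: int  # both absent
    chi2: float
    odds_ratio: float
    direction: str  # "co-occurrence" | "co-exclusion" | "undefined"
    p: float | None = None
    q: float | None = None
    skipped: bool = False
    reason: str | None = None


def presence_matrix(table) -> np.ndarray:
    """Binary detection matrix (features × samples), 1 iff abundance > 0."""
    if isinstance(table, AbundanceTable):
        values = table.data.to_numpy()
    elif isinstance(table, pd.DataFrame):
        values = table.to_numpy()
    else:
        values = np.asarray(table)
    return (values > 0).astype(np.int8)


def _odds_ratio(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _direction(or_: float) -> str:
    if or_ > 1:
        return "co-occurrence"
    if or_ < 1:
        return "co-exclusion"
    return "undefined"


def cooccurrence_test(pres_i, pres_j, name_i="i", name_j="j") -> CooccurrenceEdge:
    """Chi-squared association test of two binary presence vectors.

    A degenerate margin (a feature always present or always absent) makes
    the test undefined; the edge is returned flagged as skipped.
    """
    x = np.asarray(pres_i).astype(bool)
    y = np.asarray(pres_j).astype(bool)
    if x.shape != y.shape:
        raise ValueError("presence vectors differ in length")
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    if a + b in (0, n) or a + c in (0, n):
        return CooccurrenceEdge(
            name_i, name_j, a, b, c, d, np.nan, np.nan, "undefined",
            skipped=True, reason="degenerate margin",
        )
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    expected = np.outer([a + b, c + d], [a + c, b + d]) / n
    if (expected < 5).any():
        warnings.warn(
            f"expected cell below 5 for pair ({name_i}, {name_j})", stacklevel=2
        )
    or_ = _odds_ratio(a, b, c, d)
    p = float(stats.chi2.sf(chi2, df=1))
    return CooccurrenceEdge(name_i, name_j, a, b, c, d, float(chi2), or_, _direction(or_), p=p)


def _chi2_matrix(pres: np.ndarray):
    """Vectorized chi² / OR over all pairs of a samples × features binary matrix.

    Returns (chi2, odds_ratio, degenerate_mask) as p × p arrays.
    """
    pres = pres.astype(float)
    n, p = pres.shape
    m = pres.sum(axis=0)  # presence count per feature
    a = pres.T @ pres
    b = m[:, None] - a
    c = m[None, :] - a
    d = n - a - b - c
    degen = (m == 0) | (m == n)
    degen_pair = degen[:, None] | degen[None, :]
    denom = m[:, None] * (n - m)[:, None] * m[None, :] * (n - m)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    chi2[degen_pair] = np.nan
    zero = np.minimum.reduce([a, b, c, d]) == 0
    aa, bb, cc, dd = (x + 0.5 * zero for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        or_ = (aa * dd) / (bb * cc)
    or_[degen_pair] = np.nan
    return chi2, or_, degen_pair


def cooccurrence_network(
    table, n_perm: int = 100, seed=None, cohort: str | None = None
) -> pd.DataFrame:
    """All-pairs co-occurrence network with permutation p-values and FDR.

    Each permutation shuffles every feature's presence/absence labels across
    samples independently and recomputes the chi-squared matrix. Pairs with
    a degenerate margin (all-present or all-absent features) are skipped and
    do not enter the FDR denominator.
    """
    if isinstance(table, (AbundanceTable, pd.DataFrame)):
        feat = list(table.data.index) if isinstance(table, AbundanceTable) else list(table.index)
        pres = presence_matrix(table).T  # samples × features
    else:
        pres = np.asarray(table)
        if pres.ndim != 2:
            raise ValueError("expected a 2-D presence matrix")
        pres = pres.T
        feat = [f"F{i:03d}" for i in range(pres.shape[1])]
    n, p = pres.shape
    chi2, or_, degen = _chi2_matrix(pres)
    iu = np.triu_indices(p, k=1)
    keep = ~degen[iu]
    obs = chi2[iu][keep]

    rng = np.random.default_rng(spawn_seeds(seed, 1)[0])
    perm = np.empty((n_perm, obs.size))
    for bi in range(n_perm):
        shuf = np.empty_like(pres)
        for j in range(p):
            shuf[:, j] = pres[rng.permutation(n), j]
        chi2_b, _, degen_b = _chi2_matrix(shuf)
        vals = chi2_b[iu][keep]
        perm[bi] = np.where(np.isnan(vals), 0.0, vals)

    pvals = perm_pvalues(obs, perm)
    qvals = plugin_fdr(obs, perm)
    n_arr = np.full(obs.size, n)
    ii, jj = iu[0][keep], iu[1][keep]
    pres_f = pres.astype(float)
    m = pres_f.sum(axis=0)
    a = (pres_f.T @ pres_f)[ii, jj]
    out = pd.DataFrame(
        {
            "feature_i": [feat[i] for i in ii],
            "feature_j": [feat[j] for j in jj],
            "a": a.astype(int),
            "b": (m[ii] - a).astype(int),
            "c": (m[jj] - a).astype(int),
            "d": (n - m[ii] - m[jj] + a).astype(int),
            "chi2": obs,
            "odds_ratio": or_[iu][keep],
            "direction": [_direction(v) for v in or_[iu][keep]],
            "p_perm": pvals,
            "q": qvals,
            "n": n_arr,
        }
    )
    if cohort is not None:
        out.insert(2, "cohort", cohort)
    return out


def cell_count_direction(a: int, b: int, c: int, d: int) -> str:
    """Literal reading of the direction rule: concordant (a+d) vs discordant
    (b+c) cell totals. Kept as a config alternative to the OR rule."""
    if a + d > b + c:
        return "co-occurrence"
    if a + d < b + c:
        return "co-exclusion"
    return "undefined"
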