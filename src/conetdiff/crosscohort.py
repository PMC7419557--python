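"""Between-cohort heterogeneity, cohort specificity, key nodes, replication.

Per-cohort correlation effects are put on the Fisher-z scale (log-odds scale
for co-occurrence), pooled by inverse-variance weighting, and each edge is
tested for between-cohort heterogeneity with Cochran's Q (χ², df = cohorts−1).
Edge-level FDR comes from cohort-label permutations that keep the feature
correlation structure intact. Heterogeneous edges are classified as
cohort-specific when exactly one of the four sorted effects falls outside
Q1 − 2·IQR or Q3 + 2·IQR. Hub ("key") features are those whose count of
specific edges exceeds a cutoff calibrated from the per-permutation maxima
of false specific-edge counts per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import plugin_fdr_pvalues, spawn_seeds
from ._stats import fdr_threshold as operational_fdr_threshold
from .sparcc import _counts_matrix, sparcc

RHO_CLAMP = 0.999999


class FisherZ(NamedTuple):
    z: float
    se: float
    clamped: bool = False


def fisher_z(rho: float, n: int) -> FisherZ:
    """Fisher z-transform of a correlation with se = 1/sqrt(n − 3).

    |ρ| ≥ 1 (possible after SparCC clamping) is pulled to ±0.999999 and
    flagged rather than propagating an infinite effect.
    """
    if n <= 3:
        raise ValueError("need n > 3 for the Fisher-z standard error")
    clamped = abs(rho) >= 1
    r = float(np.clip(rho, -RHO_CLAMP, RHO_CLAMP))
    return FisherZ(float(np.arctanh(r)), 1.0 / np.sqrt(n - 3), clamped)


def log_odds_effect(a, b, c, d) -> FisherZ:
    """log OR with se = sqrt(Σ 1/cell), cells +0.5-corrected if any is zero."""
    cells = np.array([a, b, c, d], dtype=float)
    if cells.min() == 0:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    return FisherZ(float(np.log(a_ * d_ / (b_ * c_))), float(np.sqrt((1 / cells).sum())))


@dataclass
class HeterogeneityRecord:
    """Cochran-Q summary for one feature pair across cohorts."""

    pair: tuple[str, str]
    z: dict[str, float]
    se: dict[str, float]
    pooled: float
    Q: float
    df: int
    p: float
    q_perm: float | None = None
    classification: str = "indeterminate"
    untestable: bool = False


def cochran_q(effects) -> HeterogeneityRecord:
    """Fixed-effect Cochran-Q heterogeneity test.

    ``effects`` is a sequence of (z, se) pairs, or a mapping cohort → (z, se).
    Entries with non-finite z or se (edge incomputable in that cohort) are
    dropped with the degrees of freedom reduced accordingly.
    """
    if isinstance(effects, dict):
        labels = list(effects)
        pairs = [effects[c] for c in labels]
    else:
        pairs = list(effects)
        labels = [f"study{i}" for i in range(len(pairs))]
    z = np.array([p[0] for p in pairs], dtype=float)
    se = np.array([p[1] for p in pairs], dtype=float)
    usable = np.isfinite(z) & np.isfinite(se) & (se > 0)
    zd = dict(zip(labels, z))
    sed = dict(zip(labels, se))
    if usable.sum() < 2:
        return HeterogeneityRecord(
            ("", ""), zd, sed, np.nan, np.nan, 0, np.nan, untestable=True
        )
    w = 1.0 / se[usable] ** 2
    zbar = float(np.sum(w * z[usable]) / np.sum(w))
    q = float(np.sum(w * (z[usable] - zbar) ** 2))
    df = int(usable.sum() - 1)
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityRecord(("", ""), zd, sed, zbar, q, df, p)


def _q_pvalues(z: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Cochran-Q over edges. z, se: (n_cohorts, m). Returns (Q, p)."""
    w = 1.0 / se**2
    usable = np.isfinite(z) & np.isfinite(w)
    w = np.where(usable, w, 0.0)
    zz = np.where(usable, z, 0.0)
    wsum = w.sum(axis=0)
    zbar = (w * zz).sum(axis=0) / wsum
    q = (w * (zz - zbar[None, :]) ** 2).sum(axis=0)
    df = usable.sum(axis=0) - 1
    p = np.where(df >= 1, stats.chi2.sf(q, np.maximum(df, 1)), np.nan)
    return q, p


# ---------------------------------------------------------------------------
# per-cohort effect estimation


def cohort_effects(
    tables: dict[str, object], n_inner: int = 20, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """SparCC effects on the Fisher-z scale for every cohort and edge.

    Returns (z frame, se frame) indexed by edge (multi-index feature_i,
    feature_j with i < j) with one column per cohort.
    """
    mats, features = {}, None
    for name, t in tables.items():
        mat, feat = _counts_matrix(t)
        if features is None:
            features = feat
        elif feat != features:
            raise ValueError(f"cohort {name!r} has a different feature namespace")
        mats[name] = mat
    p = len(features)
    iu = np.triu_indices(p, k=1)
    pairs = [(features[i], features[j]) for i, j in zip(*iu)]
    seeds = spawn_seeds(seed, len(mats))
    zcols, secols = {}, {}
    for s, (name, mat) in zip(seeds, mats.items()):
        rho = sparcc(mat.T, n_inner=n_inner, seed=s)
        n = mat.shape[0]
        zcols[name] = np.arctanh(np.clip(rho[iu], -RHO_CLAMP, RHO_CLAMP))
        secols[name] = np.full(len(pairs), 1.0 / np.sqrt(n - 3))
    idx = pd.MultiIndex.from_tuples(pairs, names=["feature_i", "feature_j"])
    return pd.DataFrame(zcols, index=idx), pd.DataFrame(secols, index=idx), pairs


# ---------------------------------------------------------------------------
# IQR specificity rule


@dataclass
class SpecificityCall:
    """IQR outlier-rule outcome for one heterogeneous pair."""

    pair: tuple[str, str]
    effects: dict[str, float]
    q1: float
    q2: float
    q3: float
    iqr: float
    lower: float
    upper: float
    specific: bool
    outlier_cohort: str | None = None


#: strict outlier comparisons treat differences below this as exact ties,
#: so float round-off in the quartile interpolation cannot flip a boundary
IQR_TIE_TOL = 1e-9


def _iqr_outliers(eff: np.ndarray, method: str = "linear"):
    """Vectorized IQR rule on an (m, 4) effect matrix.

    Returns (specific mask, outlier column index, q1, q3). Quartiles use
    linear interpolation (R type 7) by default. Outlier tests are strict, so
    IQR = 0 (ties) can only flag values strictly outside Q1 = Q3. An edge is
    specific only when exactly one extreme lies outside its bound.
    """
    q1 = np.percentile(eff, 25, axis=1, method=method)
    q3 = np.percentile(eff, 75, axis=1, method=method)
    iqr = q3 - q1
    lower = q1 - 2.0 * iqr
    upper = q3 + 2.0 * iqr
    low_out = eff.min(axis=1) < lower - IQR_TIE_TOL
    high_out = eff.max(axis=1) > upper + IQR_TIE_TOL
    specific = low_out ^ high_out  # the "only one" rule
    idx = np.where(low_out, eff.argmin(axis=1), eff.argmax(axis=1))
    return specific, idx, q1, q3


def iqr_specificity(effects: dict[str, float], method: str = "linear") -> SpecificityCall:
    """Apply the quartile outlier rule to exactly four cohort-labeled effects."""
    if len(effects) != 4:
        raise ValueError("the specificity rule is defined for exactly 4 cohorts")
    labels = list(effects)
    vals = np.array([effects[c] for c in labels], dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("effects must be finite")
    specific, idx, q1, q3 = _iqr_outliers(vals[None, :], method=method)
    q2 = float(np.percentile(vals, 50, method=method))
    iqr = float(q3[0] - q1[0])
    return SpecificityCall(
        pair=("", ""),
        effects=dict(effects),
        q1=float(q1[0]),
        q2=q2,
        q3=float(q3[0]),
        iqr=iqr,
        lower=float(q1[0] - 2 * iqr),
        upper=float(q3[0] + 2 * iqr),
        specific=bool(specific[0]),
        outlier_cohort=labels[int(idx[0])] if specific[0] else None,
    )


# ---------------------------------------------------------------------------
# full cross-cohort analysis with cohort-label permutations


@dataclass
class CrossCohortResult:
    """Observed heterogeneity/specificity plus the permutation reference."""

    records: pd.DataFrame  # per edge: per-cohort z, Q, df, p, q_perm, class
    z: pd.DataFrame
    se: pd.DataFrame
    specific: pd.DataFrame  # IQR calls on heterogeneous edges
    specificity_fdr: float  # study-level average FDR (nan if no calls)
    perm_specific_counts: np.ndarray  # specific-call count per permutation
    perm_node_maxima: np.ndarray  # per-permutation max per-node false count
    key_nodes: pd.DataFrame
    p_threshold: float = np.nan
    extras: dict = field(default_factory=dict)


def _specific_frame(z: pd.DataFrame, mask: np.ndarray, method: str) -> pd.DataFrame:
    eff = z.to_numpy()[mask]
    cohorts = list(z.columns)
    specific, idx, q1, q3 = _iqr_outliers(eff, method=method)
    iqr = q3 - q1
    sub = z.index[mask]
    frame = pd.DataFrame(
        {
            "feature_i": sub.get_level_values(0),
            "feature_j": sub.get_level_values(1),
            "specific": specific,
            "outlier_cohort": [
                cohorts[i] if s else None for i, s in zip(idx, specific)
            ],
            "q1": q1,
            "q3": q3,
            "lower": q1 - 2 * iqr,
            "upper": q3 + 2 * iqr,
        }
    )
    for k, c in enumerate(cohorts):
        frame[f"z_{c}"] = eff[:, k]
    return frame[frame["specific"]].reset_index(drop=True)


def _node_counts(fi, fj) -> pd.Series:
    return pd.concat([pd.Series(fi), pd.Series(fj)]).value_counts()


def cross_cohort_analysis(
    tables: dict[str, object],
    n_perm: int = 100,
    seed=None,
    n_inner: int = 20,
    fdr_threshold: float = 0.05,
    quartile_method: str = "linear",
    edges: list[tuple[str, str]] | None = None,
) -> CrossCohortResult:
    """Heterogeneity + specificity + key-node analysis in one permutation pass.

    Observed per-cohort SparCC effects give Cochran-Q p-values per edge; each
    permutation reshuffles samples across cohorts (original sizes preserved,
    feature correlation intact), re-estimates effects and Q. Edge q_perm is
    the plug-in permutation FDR of the Q p-values. The IQR rule runs on
    heterogeneous edges (q_perm < ``fdr_threshold``); inside permutations the
    observed Q-p cutoff corresponding to that FDR is reused as the
    heterogeneity gate before applying the IQR rule, which yields the
    study-level specificity FDR and the per-feature false-count maxima used
    to calibrate the key-node cutoff.
    """
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} gives coarse FDR resolution", stacklevel=2)
    names = list(tables)
    seeds = spawn_seeds(seed, n_perm + 1)
    z, se, pairs = cohort_effects(tables, n_inner=n_inner, seed=seeds[0])
    if edges is not None:
        wanted = {tuple(sorted(e)) for e in edges}
        sel = np.array([tuple(sorted(p_)) in wanted for p_ in pairs])
        z, se = z[sel], se[sel]
        pairs = [p_ for p_, s in zip(pairs, sel) if s]
    else:
        sel = None
    q_obs, p_obs = _q_pvalues(z.to_numpy().T, se.to_numpy().T)

    # pooled sample matrix for label permutation
    mats = [_counts_matrix(tables[c])[0] for c in names]
    sizes = [m.shape[0] for m in mats]
    pooled = np.vstack(mats)
    ntot = pooled.shape[0]
    bounds = np.cumsum([0] + sizes)

    m_edges = len(pairs)
    p_perm = np.empty((n_perm, m_edges))
    z_perm = np.empty((n_perm, len(names), m_edges))
    rng = np.random.default_rng(seeds[0] ^ 0x5EED)
    iu_n = None
    for b in range(n_perm):
        order = rng.permutation(ntot)
        inner_seeds = spawn_seeds(seeds[b + 1], len(names))
        zs, ses = [], []
        for k, name in enumerate(names):
            idx = order[bounds[k] : bounds[k + 1]]
            mat = pooled[idx]
            rho = sparcc(mat.T, n_inner=n_inner, seed=inner_seeds[k])
            if iu_n is None:
                iu_n = np.triu_indices(rho.shape[0], k=1)
            zfull = np.arctanh(np.clip(rho[iu_n], -RHO_CLAMP, RHO_CLAMP))
            zs.append(zfull[sel] if sel is not None else zfull)
            ses.append(np.full(m_edges, 1.0 / np.sqrt(mat.shape[0] - 3)))
        zmat, semat = np.array(zs), np.array(ses)
        z_perm[b] = zmat
        _, p_perm[b] = _q_pvalues(zmat, semat)

    q_perm_vals = plugin_fdr_pvalues(p_obs, p_perm)
    classification = np.where(
        q_perm_vals < fdr_threshold,
        "heterogeneous",
        np.where(p_obs > 0.05, "stable", "indeterminate"),
    )
    records = pd.DataFrame(
        {"Q": q_obs, "df": np.isfinite(z.to_numpy()).sum(axis=1) - 1, "p": p_obs,
         "q_perm": q_perm_vals, "classification": classification},
        index=z.index,
    )
    for c in names:
        records[f"z_{c}"] = z[c]
        records[f"se_{c}"] = se[c]

    het_mask = classification == "heterogeneous"
    can_iqr = len(names) == 4
    if can_iqr and het_mask.any():
        specific = _specific_frame(z, het_mask, quartile_method)
    else:
        specific = pd.DataFrame(
            columns=["feature_i", "feature_j", "specific", "outlier_cohort"]
        )

    # permutation reference for specificity: the operational p threshold of
    # the FDR-controlled selection is reused as the heterogeneity gate
    # inside each permutation
    p_thresh = (
        operational_fdr_threshold(p_obs, p_perm, alpha=fdr_threshold)
        if het_mask.any()
        else -np.inf
    )
    perm_counts = np.zeros(n_perm)
    perm_maxima = np.zeros(n_perm)
    if can_iqr:
        fi = np.array([a for a, _ in pairs])
        fj = np.array([b for _, b in pairs])
        for b in range(n_perm):
            het_b = p_perm[b] <= p_thresh
            if not het_b.any():
                continue
            eff = z_perm[b][:, het_b].T  # edges × cohorts
            spec_b, _, _, _ = _iqr_outliers(eff, method=quartile_method)
            perm_counts[b] = spec_b.sum()
            if spec_b.any():
                sel = np.flatnonzero(het_b)[spec_b]
                perm_maxima[b] = _node_counts(fi[sel], fj[sel]).max()

    n_specific = len(specific)
    spec_fdr = float(np.mean(perm_counts) / n_specific) if n_specific else np.nan
    keys = key_nodes(specific, perm_maxima) if n_specific else pd.DataFrame(
        columns=["feature", "count", "cutoff", "is_key"]
    )
    return CrossCohortResult(
        records=records,
        z=z,
        se=se,
        specific=specific,
        specificity_fdr=spec_fdr,
        perm_specific_counts=perm_counts,
        perm_node_maxima=perm_maxima,
        key_nodes=keys,
        p_threshold=p_thresh,
    )


# ---------------------------------------------------------------------------
# key nodes, enrichment, replication, stratified splits


def key_node_cutoff(perm_maxima, percentile: float = 97.5, rule: str = "percentile") -> int:
    """Cutoff = smallest integer strictly above the upper bound of the
    permutation maxima distribution (97.5th percentile by default;
    ``rule='normal'`` uses mean + 1.96·SD instead)."""
    maxima = np.asarray(perm_maxima, dtype=float)
    if maxima.size < 20:
        warnings.warn("fewer than 20 permutation maxima: cutoff is unstable", stacklevel=2)
    if rule == "percentile":
        upper = np.percentile(maxima, percentile, method="linear")
    elif rule == "normal":
        upper = maxima.mean() + 1.96 * maxima.std(ddof=1)
    else:
        raise ValueError(f"unknown cutoff rule {rule!r}")
    return max(int(np.floor(upper)) + 1, 1)


def key_nodes(specific_edges: pd.DataFrame, perm_maxima, **kwargs) -> pd.DataFrame:
    """Flag features whose specific-edge count reaches the permutation cutoff."""
    cutoff = key_node_cutoff(perm_maxima, **kwargs)
    counts = _node_counts(specific_edges["feature_i"], specific_edges["feature_j"])
    return pd.DataFrame(
        {
            "feature": counts.index,
            "count": counts.to_numpy(),
            "cutoff": cutoff,
            "is_key": counts.to_numpy() >= cutoff,
        }
    ).reset_index(drop=True)


def enrichment_test(specific_calls: pd.DataFrame, cohort: str) -> tuple[float, float]:
    """Fisher's exact test of specific-call enrichment in one cohort.

    The observed split (assigned to ``cohort`` vs the rest) is compared with
    a uniform-expectation pseudo-count row (total/4 per cohort). Two-sided.
    """
    total = len(specific_calls)
    if total == 0:
        raise ValueError("no specific calls")
    k = int((specific_calls["outlier_cohort"] == cohort).sum())
    exp = int(round(total / 4))
    table = [[k, total - k], [exp, total - exp]]
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def two_group_q(z1, se1, z2, se2) -> tuple[float, float]:
    """Two-study Cochran Q = (z1−z2)²/(se1²+se2²), p from χ²(1)."""
    q = (z1 - z2) ** 2 / (se1**2 + se2**2)
    return float(q), float(stats.chi2.sf(q, 1))


def replication_compare(
    edges_discovery: pd.DataFrame, edges_replication: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Replication by non-heterogeneity between discovery and replication.

    Inputs need columns feature_i, feature_j, z, se. An edge is replicable if
    the two-group Cochran-Q p > 0.05; the directional criterion (replication
    effect significant at p < 0.05 with the same sign) is reported alongside.
    Edges missing in the replication set are excluded from the denominator.
    """
    key = ["feature_i", "feature_j"]
    merged = edges_discovery.merge(
        edges_replication, on=key, how="left", suffixes=("_disc", "_repl")
    )
    assessed = merged["z_repl"].notna()
    sub = merged[assessed].copy()
    q, p = zip(*[
        two_group_q(r.z_disc, r.se_disc, r.z_repl, r.se_repl) for r in sub.itertuples()
    ]) if len(sub) else ((), ())
    sub["Q"] = q
    sub["p"] = p
    sub["replicable"] = sub["p"] > 0.05
    wald_p = 2 * stats.norm.sf(np.abs(sub["z_repl"] / sub["se_repl"]))
    sub["directional"] = (wald_p < 0.05) & (
        np.sign(sub["z_repl"]) == np.sign(sub["z_disc"])
    )
    summary = {
        "n_discovery": len(edges_discovery),
        "n_assessed": int(assessed.sum()),
        "n_missing": int((~assessed).sum()),
        "replication_rate": float(sub["replicable"].mean()) if len(sub) else np.nan,
        "directional_rate": float(sub["directional"].mean()) if len(sub) else np.nan,
    }
    return sub, summary


def stratified_compare(
    counts,
    metadata: pd.DataFrame,
    group_col: str,
    min_n: int = 30,
    n_inner: int = 20,
    seed=None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential edges between sub-phenotype strata of one cohort.

    The cohort is split by ``group_col``; SparCC runs per level, edges are
    compared with Cochran-Q across levels, and Benjamini–Hochberg FDR <
    ``fdr_threshold`` flags differential edges.
    """
    from statsmodels.stats.multitest import multipletests

    mat, features = _counts_matrix(counts)
    labels = metadata[group_col]
    levels = [lv for lv in labels.unique() if pd.notna(lv)]
    if len(levels) < 2:
        raise ValueError("grouping label needs at least 2 levels")
    for lv in levels:
        n_lv = int((labels == lv).sum())
        if n_lv < min_n:
            raise ValueError(f"level {lv!r} has only {n_lv} samples (min {min_n})")
    seeds = spawn_seeds(seed, len(levels))
    p = mat.shape[1]
    iu = np.triu_indices(p, k=1)
    zs, ses = [], []
    sample_ids = list(
        counts.data.columns if hasattr(counts, "data") else range(mat.shape[0])
    )
    pos = {s: i for i, s in enumerate(sample_ids)}
    for s, lv in zip(seeds, levels):
        members = [pos[x] for x in metadata.index[labels == lv] if x in pos]
        sub = mat[members]
        rho = sparcc(sub.T, n_inner=n_inner, seed=s)
        zs.append(np.arctanh(np.clip(rho[iu], -RHO_CLAMP, RHO_CLAMP)))
        ses.append(np.full(len(iu[0]), 1.0 / np.sqrt(len(members) - 3)))
    q, pvals = _q_pvalues(np.array(zs), np.array(ses))
    rej, q_bh, _, _ = multipletests(pvals, alpha=fdr_threshold, method="fdr_bh")
    out = pd.DataFrame(
        {
            "feature_i": [features[i] for i in iu[0]],
            "feature_j": [features[j] for j in iu[1]],
            "Q": q,
            "p": pvals,
            "q_bh": q_bh,
            "differential": rej,
        }
    )
    for k, lv in enumerate(levels):
        out[f"z_{lv}"] = zs[k]
    return out
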