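"""Covariate adjustment, species–pathway association, contribution shares.

Cohorts differ in age and sex structure, which can induce spurious
between-feature correlation; partial correlation given the covariates
removes that component. Specificity calls are re-tested on covariate-
partialled effects (on the CLR scale, so the adjustment lives in the same
unconstrained space as the sparsifier). Species–pathway associations use
Spearman correlation of least-squares residuals after regressing out age,
sex and read depth. Contribution shares attribute a pathway's community
abundance to its stratified per-species components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import perm_pvalues, plugin_fdr, spawn_seeds
from .crosscohort import SpecificityCall, iqr_specificity
from .sparse import clr_from_counts


def partial_correlation(r_ab: float, r_ac: float, r_bc: float) -> float:
    """First-order partial correlation r_AB·C from the three marginals."""
    if abs(r_ac) >= 1 or abs(r_bc) >= 1:
        raise ValueError("degenerate conditioning: |r| with covariate is 1")
    return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))


def partial_correlation_matrix(corr: np.ndarray) -> np.ndarray:
    """All pairwise partial correlations given all remaining variables.

    Inverts the correlation matrix and normalizes the precision entries:
    r_ij·rest = −P_ij / sqrt(P_ii P_jj).
    """
    corr = np.asarray(corr, dtype=float)
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def partial_corr_xy(x, y, covariates) -> float:
    """Partial correlation of two vectors given a covariate matrix."""
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] == len(np.asarray(x)):
        cov = cov.T
    block = np.vstack([np.asarray(x, float), np.asarray(y, float), cov])
    corr = np.corrcoef(block)
    return float(partial_correlation_matrix(corr)[0, 1])


def residualize(y, covariates) -> np.ndarray:
    """Least-squares residuals of y on covariates (with intercept)."""
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != y.size:
        cov = cov.T
    design = np.column_stack([np.ones(y.size), cov])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def adjust_specificity(
    study: dict,
    specific_calls: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Re-test specificity calls on covariate-partialled CLR correlations.

    For every specific edge, each cohort's effect is recomputed as the
    partial correlation of the two features' CLR abundances given the
    covariates; the IQR rule reruns on the adjusted effects and a call
    survives only if it is still specific to the same cohort. Samples with
    missing covariate values are dropped (count recorded per cohort).
    """
    cohorts = list(study)
    clr_cache, cov_cache, dropped = {}, {}, {}
    for c in cohorts:
        cohort = study[c]
        meta = cohort.metadata
        ok = meta[list(covariates)].notna().all(axis=1)
        dropped[c] = int((~ok).sum())
        keep = meta.index[ok]
        col_idx = [cohort.counts.data.columns.get_loc(s) for s in keep]
        clr = clr_from_counts(cohort.counts)[col_idx]
        clr_cache[c] = clr
        cov_cache[c] = meta.loc[keep, list(covariates)].to_numpy(dtype=float)
    feat_pos = {
        f: i for i, f in enumerate(study[cohorts[0]].counts.data.index)
    }
    rows = []
    for row in specific_calls.itertuples():
        i, j = feat_pos[row.feature_i], feat_pos[row.feature_j]
        adj = {}
        for c in cohorts:
            clr = clr_cache[c]
            r = partial_corr_xy(clr[:, i], clr[:, j], cov_cache[c])
            # Fisher z keeps the adjusted effects on the scale the original
            # specificity calls were made on
            adj[c] = float(np.arctanh(np.clip(r, -0.999999, 0.999999)))
        call: SpecificityCall = iqr_specificity(adj, method=quartile_method)
        survives = call.specific and call.outlier_cohort == row.outlier_cohort
        rec = {
            "feature_i": row.feature_i,
            "feature_j": row.feature_j,
            "outlier_cohort": row.outlier_cohort,
            "adjusted_outlier": call.outlier_cohort,
            "survives": survives,
        }
        rec.update({f"partial_{c}": adj[c] for c in cohorts})
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["dropped_samples"] = dropped
    return out


def species_pathway_association(
    species: pd.DataFrame,
    pathways: pd.DataFrame,
    metadata: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    covariates: tuple[str, ...] = ("age", "sex", "read_depth"),
    n_perm: int = 100,
    seed=None,
) -> pd.DataFrame:
    """Spearman species–pathway association after covariate residualization.

    Both abundance vectors are residualized on the covariates by least
    squares; Spearman's ρ is computed on the residuals, with a permutation
    p-value and plug-in FDR obtained by shuffling the pathway residuals.
    ``species``/``pathways`` are feature × sample frames sharing samples.
    """
    samples = [s for s in species.columns if s in pathways.columns]
    if len(samples) < 30:
        raise ValueError("need at least 30 shared samples")
    cov = metadata.loc[samples, list(covariates)].to_numpy(dtype=float)
    if pairs is None:
        pairs = [(sp, pw) for sp in species.index for pw in pathways.index]
    res_sp = {
        sp: residualize(species.loc[sp, samples].to_numpy(float), cov)
        for sp in {a for a, _ in pairs}
    }
    res_pw = {
        pw: residualize(pathways.loc[pw, samples].to_numpy(float), cov)
        for pw in {b for _, b in pairs}
    }
    rng = np.random.default_rng(spawn_seeds(seed, 1)[0])
    n = len(samples)
    rhos, testable = [], []
    for sp, pw in pairs:
        a, b = res_sp[sp], res_pw[pw]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rhos.append(np.nan)
            testable.append(False)
        else:
            rhos.append(stats.spearmanr(a, b).statistic)
            testable.append(True)
    rhos = np.asarray(rhos)
    obs = np.abs(rhos[testable])
    perm = np.empty((n_perm, obs.size))
    idx_testable = [k for k, t in enumerate(testable) if t]
    ranks_a = {sp: stats.rankdata(v) for sp, v in res_sp.items()}
    ranks_b = {pw: stats.rankdata(v) for pw, v in res_pw.items()}
    for bi in range(n_perm):
        shuffle = rng.permutation(n)
        col = []
        for k in idx_testable:
            sp, pw = pairs[k]
            ra, rb = ranks_a[sp], ranks_b[pw][shuffle]
            col.append(abs(np.corrcoef(ra, rb)[0, 1]))
        perm[bi] = col
    pv = np.full(len(pairs), np.nan)
    qv = np.full(len(pairs), np.nan)
    pv[idx_testable] = perm_pvalues(obs, perm)
    qv[idx_testable] = plugin_fdr(obs, perm)
    return pd.DataFrame(
        {
            "species": [a for a, _ in pairs],
            "pathway": [b for _, b in pairs],
            "rho": rhos,
            "p_perm": pv,
            "q": qv,
            "testable": testable,
            "n": n,
        }
    )


def species_contribution(
    community: pd.DataFrame,
    stratified: pd.DataFrame,
    cohorts: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-species contribution shares to each pathway's community abundance.

    ``stratified`` rows are named "pathway|species" (HUMAnN2 dialect); the
    share is stratified ÷ community per sample (0 where the community
    abundance is 0), summarized as the mean share (per cohort when cohort
    labels are given), with the top contributor flagged per pathway.
    """
    recs = []
    for row in stratified.index:
        if "|" not in row:
            raise ValueError(f"stratified row {row!r} lacks the 'pathway|species' form")
        pw, sp = row.split("|", 1)
        if pw not in community.index:
            raise ValueError(f"stratified pathway {pw!r} missing from community table")
        comm = community.loc[pw].to_numpy(dtype=float)
        strat = stratified.loc[row].to_numpy(dtype=float)
        excess = strat > comm * 1.01 + 1e-12
        if excess.any():
            raise ValueError(
                f"stratified abundance exceeds community total for {row!r}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(comm > 0, strat / np.where(comm > 0, comm, 1.0), 0.0)
        if cohorts is not None:
            lab = cohorts.loc[stratified.columns].to_numpy()
            for c in pd.unique(lab):
                recs.append(
                    {"pathway": pw, "species": sp, "cohort": c,
                     "mean_share": float(share[lab == c].mean())}
                )
        else:
            recs.append(
                {"pathway": pw, "species": sp, "cohort": "all",
                 "mean_share": float(share.mean())}
            )
    out = pd.DataFrame(recs)
    out["top_contributor"] = False
    for (pw, c), grp in out.groupby(["pathway", "cohort"]):
        out.loc[grp["mean_share"].idxmax(), "top_contributor"] = True
    return out


def contribution_shift_test(shares_a, shares_b) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of per-sample shares between two cohorts."""
    res = stats.mannwhitneyu(shares_a, shares_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
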