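"""Ground-truth benchmark studies exercising every pipeline stage.

Each benchmark builds a synthetic multi-cohort study under fixed,
documented conditions, runs the corresponding pipeline stage and scores the
result against the generator's truth. The same functions back the test
suite and the reproduction script, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import spawn_seeds
from .cooccur import cooccurrence_network
from .covariates import adjust_specificity, partial_corr_xy
from .crosscohort import (
    RHO_CLAMP,
    cross_cohort_analysis,
    replication_compare,
)
from .sparcc import permutation_edge_test, sparcc
from .sparse import clr_from_counts
from .synth import make_basis_network, make_study, simulate_cohort

COHORTS = ("C1", "C2", "C3", "C4")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))


def sparcc_recovery(seed=0, p=30, n_edges=12, rho=0.6, n=400, depth=50_000,
                    n_perm=100, n_inner=20) -> dict:
    """Planted-edge recovery of the SparCC stage in one cohort.

    Reports the mean absolute error of the estimates on planted edges
    (against realized post-projection truth), sensitivity and empirical FDR
    of the q < 0.05 edge set.
    """
    s1, s2, s3 = spawn_seeds(seed, 3)
    truth = make_basis_network(p, n_edges, rho, seed=s1)
    cohort = simulate_cohort(truth, "C1", n, depth, seed=s2)
    edges = permutation_edge_test(cohort.counts, n_perm=n_perm, seed=s3, n_inner=n_inner)
    feats = truth.features
    planted = {_pair_key(feats[i], feats[j]): v for i, j, v in truth.edges}
    keys = [_pair_key(a, b) for a, b in zip(edges["feature_i"], edges["feature_j"])]
    is_planted = np.array([k in planted for k in keys])
    truth_vals = np.array([planted.get(k, 0.0) for k in keys])
    mae = float(np.abs(edges["rho"].to_numpy() - truth_vals)[is_planted].mean())
    sig = (edges["q"] < 0.05).to_numpy()
    sensitivity = float(sig[is_planted].mean())
    n_sig = int(sig.sum())
    fdr = float(sig[~is_planted].sum() / n_sig) if n_sig else 0.0
    return {
        "mae_planted": mae,
        "sensitivity": sensitivity,
        "empirical_fdr": fdr,
        "n_significant": n_sig,
        "n_edges_tested": len(edges),
    }


def null_calibration(seed=0, p=30, n=400, depth=50_000, n_perm=100,
                     n_inner=20, pi=0.3) -> dict:
    """Permutation-p calibration on data with no correlation structure.

    Co-abundance: identity basis network; fraction of edges with
    permutation p ≤ 0.05 should sit near the nominal level. Co-occurrence:
    independent zero-inflation at rate ``pi`` gives presence/absence
    variation with no true association.
    """
    s1, s2, s3, s4, s5 = spawn_seeds(seed, 5)
    truth = make_basis_network(p, 0, 0.0, seed=s1)
    cohort = simulate_cohort(truth, "C1", n, depth, seed=s2)
    edges = permutation_edge_test(cohort.counts, n_perm=n_perm, seed=s3, n_inner=n_inner)
    frac_ab = float((edges["p_perm"] <= 0.05).mean())

    truth0 = make_basis_network(p, 0, 0.0, seed=s1)
    truth0.pi = np.full(p, pi)
    cohort0 = simulate_cohort(truth0, "C1", n, depth, seed=s4)
    net = cooccurrence_network(cohort0.abundance, n_perm=n_perm, seed=s5)
    frac_co = float((net["p_perm"] <= 0.05).mean()) if len(net) else np.nan
    return {
        "coabundance_p05_fraction": frac_ab,
        "cooccurrence_p05_fraction": frac_co,
        "n_cooccurrence_pairs": int(len(net)),
    }


def heterogeneity_null(seed=0, p=21, n=300, depth=50_000, n_shared=6,
                       rho_shared=0.4, n_perm=100, n_inner=20) -> dict:
    """Cochran-Q null uniformity: 4 cohorts drawn from one shared truth.

    Returns the Kolmogorov–Smirnov p-value of the observed Q p-values
    against uniform and the heterogeneous fraction at q_perm < 0.05.
    """
    s1, *cseeds = spawn_seeds(seed, 6)
    truth = make_basis_network(p, n_shared, rho_shared, seed=s1, cohorts=COHORTS)
    study = {
        c: simulate_cohort(truth, c, n, depth, seed=cs)
        for c, cs in zip(COHORTS, cseeds[:4])
    }
    res = cross_cohort_analysis(
        {c: s.counts for c, s in study.items()},
        n_perm=n_perm, seed=cseeds[4], n_inner=n_inner,
    )
    pvals = res.records["p"].to_numpy()
    ks = stats.kstest(pvals, "uniform")
    return {
        "ks_pvalue": float(ks.pvalue),
        "null_het_fraction": float(
            (res.records["classification"] == "heterogeneous").mean()
        ),
        "n_edges": len(pvals),
    }


def heterogeneity_power(seed=0, p=21, n=300, depth=50_000, delta_z=0.4,
                        n_planted=10, n_perm=100, n_inner=20) -> dict:
    """Power to detect a one-cohort effect shift of Δz on planted edges."""
    rho_shift = float(np.tanh(delta_z))
    planted = [
        {"i": 2 * k, "j": 2 * k + 1, "cohort": "C4", "rho": rho_shift}
        for k in range(n_planted)
    ]
    cfg = {
        "cohorts": [{"name": c, "n": n} for c in COHORTS],
        "p": p, "n_edges": 0, "rho": 0.0, "depth": depth, "planted": planted,
    }
    s1, s2 = spawn_seeds(seed, 2)
    study = make_study(cfg, seed=s1)
    res = cross_cohort_analysis(
        {c: s.counts for c, s in study.items()},
        n_perm=n_perm, seed=s2, n_inner=n_inner,
    )
    feats = study["C1"].truth.features
    planted_keys = {
        _pair_key(feats[e["i"]], feats[e["j"]]) for e in planted
    }
    rec = res.records.reset_index()
    hit = rec.apply(
        lambda r: _pair_key(r["feature_i"], r["feature_j"]) in planted_keys, axis=1
    )
    power = float((rec.loc[hit, "q_perm"] < 0.05).mean())
    return {"power": power, "n_planted": n_planted}


def specificity_study_config(n=300, depth=50_000) -> tuple[dict, list, list]:
    """The combined cohort-specificity / key-node study.

    One hub feature carries 15 cohort-specific edges at ρ = 0.6 (3–4 per
    cohort; its partner features share within-quartet correlations of 0.4 in
    every cohort, which keeps each cohort's Σ positive definite without
    making the partner edges heterogeneous). Ten scattered specific edges at
    ρ = 0.6, assigned across cohorts, sit on separate background features
    with at most two specific edges per feature. All on p = 30 features.
    """
    partners = {"C1": [1, 2, 3, 4], "C2": [5, 6, 7, 8],
                "C3": [9, 10, 11, 12], "C4": [13, 14, 15]}
    shared = [
        {"i": ps[a], "j": ps[b], "rho": 0.4}
        for ps in partners.values()
        for a in range(len(ps)) for b in range(a + 1, len(ps))
    ]
    hub_edges = [
        {"i": 0, "j": j, "cohort": c, "rho": 0.6}
        for c, ps in partners.items() for j in ps
    ]
    scattered = [
        ((16, 17), "C1"), ((18, 19), "C2"), ((20, 21), "C3"), ((22, 23), "C4"),
        ((24, 25), "C1"), ((26, 27), "C2"), ((28, 29), "C3"), ((16, 18), "C2"),
        ((17, 19), "C3"), ((20, 22), "C1"),
    ]
    planted = hub_edges + [
        {"i": i, "j": j, "cohort": c, "rho": 0.6} for (i, j), c in scattered
    ]
    cfg = {
        "cohorts": [{"name": c, "n": n} for c in COHORTS],
        "p": 30, "n_edges": 0, "rho": 0.0, "depth": depth,
        "shared_edges": shared, "planted": planted,
    }
    return cfg, scattered, hub_edges


def specificity_recovery(seed=0, n=300, depth=50_000, n_perm=50, n_inner=20) -> dict:
    """Recovery of planted cohort-specific edges and the key hub feature."""
    cfg, scattered, hub_edges = specificity_study_config(n=n, depth=depth)
    s1, s2 = spawn_seeds(seed, 2)
    study = make_study(cfg, seed=s1)
    res = cross_cohort_analysis(
        {c: s.counts for c, s in study.items()},
        n_perm=n_perm, seed=s2, n_inner=n_inner,
    )
    feats = study["C1"].truth.features
    calls = {
        (_pair_key(a, b), c)
        for a, b, c in zip(
            res.specific["feature_i"], res.specific["feature_j"],
            res.specific["outlier_cohort"],
        )
    }
    scattered_hit = sum(
        ( _pair_key(feats[i], feats[j]), c) in calls for (i, j), c in scattered
    )
    hub_name = feats[0]
    kn = res.key_nodes
    hub_row = kn[kn["feature"] == hub_name]
    hub_count = int(hub_row["count"].iloc[0]) if len(hub_row) else 0
    cutoff = int(kn["cutoff"].iloc[0]) if len(kn) else 0
    truth_pairs = {
        _pair_key(feats[e["i"]], feats[e["j"]])
        for e in hub_edges
    } | {_pair_key(feats[i], feats[j]) for (i, j), _ in scattered}
    false_calls = sum(1 for k, _ in calls if k not in truth_pairs)
    return {
        "scattered_recovered": int(scattered_hit),
        "n_scattered": len(scattered),
        "hub_specific_count": hub_count,
        "hub_is_key": bool(hub_row["is_key"].iloc[0]) if len(hub_row) else False,
        "keynode_cutoff": cutoff,
        "n_specific_calls": int(len(res.specific)),
        "false_specific_calls": int(false_calls),
        "specificity_fdr": float(res.specificity_fdr),
        "study": study,
        "result": res,
    }


def confounding_removal(seed=0, p=100, n=2000, depth=50_000, loading=0.055,
                        feature_sd=1.3) -> dict:
    """An age-confounded feature pair: marginal vs age-partialled correlation.

    Two otherwise independent features load on age; their CLR abundances
    correlate marginally (loading and spread calibrated so the marginal
    correlation is near 0.25) but the partial correlation given age
    vanishes. The feature count keeps the compositional closure artifact of
    the CLR small relative to that target.
    """
    s1, s2 = spawn_seeds(seed, 2)
    truth = make_basis_network(p, 0, 0.0, seed=s1)
    load = np.zeros(p)
    load[[0, 1]] = loading
    truth.age_loading = load
    truth.sds = np.full(p, 1.0)
    truth.sds[[0, 1]] = feature_sd
    cohort = simulate_cohort(truth, "C1", n, depth, seed=s2)
    clr = clr_from_counts(cohort.counts)
    age = cohort.metadata["age"].to_numpy(float)
    marginal = float(np.corrcoef(clr[:, 0], clr[:, 1])[0, 1])
    partial = float(partial_corr_xy(clr[:, 0], clr[:, 1], age))
    return {"marginal_r": marginal, "partial_r": partial}


def confounded_specificity(seed=0, p=20, n=300, depth=50_000, loading=0.15,
                           n_perm=50, n_inner=20) -> dict:
    """A specificity call induced purely by one cohort's age effect.

    Features 0 and 1 load on age only in cohort C4, creating a C4-specific
    apparent co-abundance; partialling out age should remove the call. The
    loading is strong (induced r well above 0.6) so the benchmark exercises
    the adjustment rather than the outlier rule's marginal recall.
    """
    load = [loading if k < 2 else 0.0 for k in range(p)]
    cfg = {
        "cohorts": [
            {"name": c, "n": n, **({"age_loading": load} if c == "C4" else {})}
            for c in COHORTS
        ],
        "p": p, "n_edges": 0, "rho": 0.0, "depth": depth,
    }
    s1, s2 = spawn_seeds(seed, 2)
    study = make_study(cfg, seed=s1)
    res = cross_cohort_analysis(
        {c: s.counts for c, s in study.items()},
        n_perm=n_perm, seed=s2, n_inner=n_inner,
    )
    feats = study["C1"].truth.features
    target = _pair_key(feats[0], feats[1])
    spec = res.specific
    called = [
        (r.feature_i, r.feature_j, r.outlier_cohort)
        for r in spec.itertuples()
        if _pair_key(r.feature_i, r.feature_j) == target
    ]
    called_before = bool(called) and called[0][2] == "C4"
    survives = None
    if called_before:
        adjusted = adjust_specificity(study, spec, covariates=("age", "sex"))
        row = adjusted[
            adjusted.apply(
                lambda r: _pair_key(r["feature_i"], r["feature_j"]) == target, axis=1
            )
        ]
        survives = bool(row["survives"].iloc[0])
    return {"called_before_adjustment": called_before,
            "removed_after_adjustment": (called_before and not survives)}


def replication_benchmark(seed=0, p=30, n_edges=12, rho=0.6, n=300,
                          depth=50_000, n_perm=100, n_inner=20) -> dict:
    """Split-sample self-replication of one cohort's co-abundance network."""
    s1, s2, s3, s4 = spawn_seeds(seed, 4)
    truth = make_basis_network(p, n_edges, rho, seed=s1)
    disc = simulate_cohort(truth, "D", n, depth, seed=s2)
    repl = simulate_cohort(truth, "R", n, depth, seed=s3)
    edges = permutation_edge_test(disc.counts, n_perm=n_perm, seed=s4, n_inner=n_inner)
    sig = edges[edges["q"] < 0.05].copy()
    sig["z"] = np.arctanh(np.clip(sig["rho"], -RHO_CLAMP, RHO_CLAMP))
    sig["se"] = 1.0 / np.sqrt(n - 3)
    rho_r = sparcc(repl.counts, n_inner=n_inner, seed=s4 ^ 0x7E57)
    feats = truth.features
    pos = {f: i for i, f in enumerate(feats)}
    repl_frame = pd.DataFrame(
        {
            "feature_i": sig["feature_i"],
            "feature_j": sig["feature_j"],
            "z": [
                float(np.arctanh(np.clip(rho_r[pos[a], pos[b]], -RHO_CLAMP, RHO_CLAMP)))
                for a, b in zip(sig["feature_i"], sig["feature_j"])
            ],
            "se": 1.0 / np.sqrt(n - 3),
        }
    )
    disc_frame = sig[["feature_i", "feature_j", "z", "se"]]
    _, summary = replication_compare(disc_frame, repl_frame)
    _, self_summary = replication_compare(disc_frame, disc_frame)
    return {
        "replication_rate": summary["replication_rate"],
        "directional_rate": summary["directional_rate"],
        "n_discovery_edges": summary["n_discovery"],
        "self_replication_rate": self_summary["replication_rate"],
    }
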