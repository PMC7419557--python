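"""Cochran-Q heterogeneity, IQR specificity, key nodes, replication."""

import itertools

import numpy as np
import pandas as pd
import pytest

import conetdiff as cd
from conetdiff.crosscohort import (
    key_node_cutoff,
    log_odds_effect,
    two_group_q,
)


def oracle_cochran_q(pairs):
    """Textbook fixed-effect meta-analysis, coded independently."""
    w = [1.0 / se**2 for _, se in pairs]
    zbar = sum(wi * z for wi, (z, _) in zip(w, pairs)) / sum(w)
    q = sum(wi * (z - zbar) ** 2 for wi, (z, _) in zip(w, pairs))
    return q, zbar


def oracle_iqr_specific(effects, tol=1e-9):
    """Quartile outlier rule by explicit type-7 interpolation on 4 values."""
    b = sorted(effects)
    q1 = b[0] + 0.75 * (b[1] - b[0])
    q3 = b[2] + 0.25 * (b[3] - b[2])
    iqr = q3 - q1
    low = b[0] < q1 - 2 * iqr - tol
    high = b[3] > q3 + 2 * iqr + tol
    if low == high:  # none, or both extremes: not specific
        return False, None
    idx = int(np.argmin(effects)) if low else int(np.argmax(effects))
    return True, idx


class TestFisherZ:
    def test_values_and_antisymmetry(self):
        z, se, _ = cd.fisher_z(0.5, 103)
        assert z == pytest.approx(0.5493, abs=1e-4)
        assert se == pytest.approx(0.1)
        assert cd.fisher_z(0.0, 10).z == 0.0
        assert cd.fisher_z(-0.7, 50).z == pytest.approx(-cd.fisher_z(0.7, 50).z)

    def test_clamped_at_unit_correlation(self):
        res = cd.fisher_z(1.0, 100)
        assert res.clamped and np.isfinite(res.z)

    def test_log_odds_effect_zero_cell_correction(self):
        eff = log_odds_effect(10, 0, 5, 20)
        assert np.isfinite(eff.z) and np.isfinite(eff.se)


class TestCochranQ:
    def test_equal_effects_give_zero(self):
        rec = cd.cochran_q([(0.5, 0.1)] * 4)
        assert rec.Q == pytest.approx(0.0, abs=1e-12)
        assert rec.p == pytest.approx(1.0)

    def test_hand_value(self):
        rec = cd.cochran_q([(0, 0.1), (0, 0.1), (0, 0.1), (1, 0.1)])
        assert rec.Q == pytest.approx(75.0, rel=1e-12)
        assert rec.df == 3
        assert rec.pooled == pytest.approx(0.25)

    def test_se_scaling_homogeneity(self):
        base = [(0.1, 0.1), (0.4, 0.2), (-0.2, 0.15)]
        q1 = cd.cochran_q(base).Q
        q2 = cd.cochran_q([(z, 2 * se) for z, se in base]).Q
        assert q2 == pytest.approx(q1 / 4)

    def test_oracle_agreement_on_random_inputs(self):
        r = np.random.default_rng(11)
        for _ in range(100):
            k = r.integers(2, 6)
            pairs = [(r.normal(), r.uniform(0.05, 0.5)) for _ in range(k)]
            rec = cd.cochran_q(pairs)
            q_ref, zbar_ref = oracle_cochran_q(pairs)
            assert rec.Q == pytest.approx(q_ref, abs=1e-10)
            assert rec.pooled == pytest.approx(zbar_ref, abs=1e-12)

    def test_nan_cohorts_dropped_with_df(self):
        rec = cd.cochran_q([(0.5, 0.1), (np.nan, 0.1), (0.2, 0.1)])
        assert rec.df == 1
        untest = cd.cochran_q([(0.5, 0.1), (np.nan, 0.1)])
        assert untest.untestable


class TestIqrSpecificity:
    def test_worked_example(self):
        call = cd.iqr_specificity({"A": 0.10, "B": 0.11, "C": 0.12, "D": 0.60})
        assert call.q1 == pytest.approx(0.1075)
        assert call.q3 == pytest.approx(0.24)
        assert call.upper == pytest.approx(0.505)
        assert call.specific and call.outlier_cohort == "D"

    def test_sign_flip_symmetry(self):
        call = cd.iqr_specificity({"A": -0.60, "B": -0.12, "C": -0.11, "D": -0.10})
        assert call.specific and call.outlier_cohort == "A"

    def test_ties_not_specific(self):
        call = cd.iqr_specificity({c: 0.3 for c in "ABCD"})
        assert not call.specific and call.outlier_cohort is None

    def test_symmetric_double_outlier_never_specific(self):
        call = cd.iqr_specificity({"A": -0.9, "B": -0.01, "C": 0.01, "D": 0.9})
        assert not call.specific

    def test_grid_oracle_agreement(self):
        # coarse grid here; the exhaustive grid runs in the acceptance suite
        grid = np.round(np.arange(-1.0, 1.0001, 0.25), 10)
        for combo in itertools.combinations_with_replacement(grid, 4):
            call = cd.iqr_specificity(dict(zip("ABCD", combo)))
            ref_specific, ref_idx = oracle_iqr_specific(list(combo))
            assert call.specific == ref_specific
            if ref_specific:
                assert call.outlier_cohort == "ABCD"[ref_idx]

    def test_requires_four_cohorts(self):
        with pytest.raises(ValueError):
            cd.iqr_specificity({"A": 0.1, "B": 0.2})


class TestKeyNodes:
    def test_constant_maxima_cutoff(self):
        cutoff = key_node_cutoff(np.full(100, 7))
        assert cutoff == 8
        edges = pd.DataFrame(
            {"feature_i": ["hub"] * 15, "feature_j": [f"x{i}" for i in range(15)]}
        )
        kn = cd.key_nodes(edges, np.full(100, 7))
        hub = kn[kn["feature"] == "hub"].iloc[0]
        assert hub["count"] == 15 and hub["is_key"]
        assert not kn[kn["feature"] != "hub"]["is_key"].any()

    def test_cutoff_monotone_in_maxima_distribution(self):
        lo = key_node_cutoff(np.r_[np.zeros(80), np.ones(20)])
        hi = key_node_cutoff(np.r_[np.zeros(40), np.full(60, 5)])
        assert hi >= lo

    def test_no_node_reaches_cutoff(self):
        edges = pd.DataFrame({"feature_i": ["a"], "feature_j": ["b"]})
        kn = cd.key_nodes(edges, np.full(50, 6))
        assert not kn["is_key"].any()


class TestEnrichment:
    def test_uniform_assignment_is_null(self):
        calls = pd.DataFrame({"outlier_cohort": ["A", "B", "C", "D"] * 5})
        or_, p = cd.enrichment_test(calls, "A")
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_concentration_strengthens_enrichment(self):
        pvals = []
        for k in (8, 16, 32):
            calls = pd.DataFrame({"outlier_cohort": ["A"] * k + ["B", "C", "D"]})
            pvals.append(cd.enrichment_test(calls, "A")[1])
        assert pvals[0] > pvals[1] > pvals[2]

    def test_single_call_has_no_power(self):
        calls = pd.DataFrame({"outlier_cohort": ["A"]})
        _, p = cd.enrichment_test(calls, "A")
        assert p == 1.0


class TestReplication:
    def test_identical_inputs_fully_replicable(self):
        edges = pd.DataFrame(
            {
                "feature_i": ["a", "b"],
                "feature_j": ["c", "d"],
                "z": [0.5, -0.3],
                "se": [0.1, 0.1],
            }
        )
        per_edge, summary = cd.replication_compare(edges, edges)
        assert (per_edge["Q"] == 0).all()
        assert summary["replication_rate"] == 1.0

    def test_opposite_strong_effects_not_replicable(self):
        q, p = two_group_q(0.6, 0.08, -0.6, 0.08)
        assert q == pytest.approx(112.5)
        assert p < 1e-10

    def test_missing_replication_edges_excluded(self):
        disc = pd.DataFrame(
            {"feature_i": ["a", "b"], "feature_j": ["c", "d"],
             "z": [0.5, 0.2], "se": [0.1, 0.1]}
        )
        repl = disc.iloc[:1]
        _, summary = cd.replication_compare(disc, repl)
        assert summary["n_assessed"] == 1 and summary["n_missing"] == 1


class TestStratifiedCompare:
    def test_copied_groups_have_no_differential_edges(self, small_cohort):
        counts = small_cohort.counts
        meta = small_cohort.metadata.copy()
        half = len(meta) // 2
        meta["grp"] = ["u"] * half + ["v"] * (len(meta) - half)
        # identical groups: duplicate the same samples under both labels
        dup = cd.CountTable(
            pd.concat([counts.data, counts.data.add_suffix("_copy")], axis=1)
        )
        meta2 = pd.concat(
            [meta.assign(grp="u"), meta.assign(grp="v", sample=meta["sample"] + "_copy")]
        ).set_index("sample", drop=False)
        out = cd.stratified_compare(dup, meta2, "grp", n_inner=1, seed=5)
        assert not out["differential"].any()

    def test_planted_subtype_difference_flagged(self):
        truth = cd.make_basis_network(10, 0, 0.0, seed=21, cohorts=("U", "V"))
        strong = cd.plant_specific_edge(truth, (0, 1), "U", 0.6)
        u = cd.simulate_cohort(strong, "U", 200, 30_000, seed=22)
        v = cd.simulate_cohort(strong, "V", 200, 30_000, seed=23)
        counts = cd.CountTable(pd.concat([u.counts.data, v.counts.data], axis=1))
        meta = pd.concat([u.metadata, v.metadata])
        meta["subtype"] = ["U"] * 200 + ["V"] * 200
        out = cd.stratified_compare(counts, meta, "subtype", n_inner=5, seed=24)
        row = out[(out["feature_i"] == truth.features[0])
                  & (out["feature_j"] == truth.features[1])]
        assert row["differential"].iloc[0]
        assert out["differential"].sum() <= 3

    def test_small_level_rejected_by_name(self, small_cohort):
        meta = small_cohort.metadata.copy()
        meta["grp"] = ["tiny"] * 5 + ["big"] * (len(meta) - 5)
        with pytest.raises(ValueError, match="tiny"):
            cd.stratified_compare(small_cohort.counts, meta, "grp")


@pytest.fixture(scope="module")
def study_result():
    cfg = {
            "cohorts": [{"name": c, "n": 120} for c in ("A", "B", "C", "D")],
        "p": 10,
        "n_edges": 0,
        "rho": 0.0,
        "depth": 20_000,
        "planted": [{"i": 0, "j": 1, "cohort": "D", "rho": 0.7}],
    }
    study = cd.make_study(cfg, seed=31)
    res = cd.cross_cohort_analysis(
        {n: c.counts for n, c in study.items()},
        n_perm=30,
        seed=32,
        n_inner=5,
    )
    return study, res


class TestCrossCohortAnalysis:
    def test_planted_edge_heterogeneous_and_specific(self, study_result):
        study, res = study_result
        feats = study["A"].truth.features
        rec = res.records.loc[(feats[0], feats[1])]
        assert rec["classification"] == "heterogeneous"
        spec = res.specific
        hit = spec[(spec["feature_i"] == feats[0]) & (spec["feature_j"] == feats[1])]
        assert len(hit) == 1 and hit["outlier_cohort"].iloc[0] == "D"

    def test_classification_partition(self, study_result):
        _, res = study_result
        rec = res.records
        het = rec["classification"] == "heterogeneous"
        assert (rec.loc[het, "q_perm"] < 0.05).all()
        stable = rec["classification"] == "stable"
        assert (rec.loc[stable, "p"] > 0.05).all()

    def test_edge_subset_restriction(self, study_result):
        study, _ = study_result
        feats = study["A"].truth.features
        res = cd.cross_cohort_analysis(
            {n: c.counts for n, c in study.items()},
            n_perm=25,
            seed=33,
            n_inner=3,
            edges=[(feats[0], feats[1]), (feats[2], feats[3])],
        )
        assert len(res.records) == 2
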