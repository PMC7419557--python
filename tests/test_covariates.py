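"""Partial correlations, covariate adjustment, contribution shares."""

import numpy as np
import pandas as pd
import pytest

import conetdiff as cd
from conetdiff.covariates import contribution_shift_test, partial_corr_xy, residualize


class TestPartialCorrelation:
    def test_closed_form(self):
        assert cd.partial_correlation(0.6, 0.5, 0.5) == pytest.approx(0.35 / 0.75)
        assert cd.partial_correlation(0.3, 0.0, 0.0) == pytest.approx(0.3)

    def test_exchangeable_in_a_and_b(self):
        assert cd.partial_correlation(0.4, 0.3, 0.6) == pytest.approx(
            cd.partial_correlation(0.4, 0.6, 0.3)
        )

    def test_matrix_route_matches_closed_form(self):
        r = np.random.default_rng(1)
        for _ in range(20):
            # random PD 3x3 correlation via a random factor model
            a = r.standard_normal((3, 3))
            cov = a @ a.T + np.eye(3)
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            closed = cd.partial_correlation(corr[0, 1], corr[0, 2], corr[1, 2])
            matrix = cd.partial_correlation_matrix(corr)[0, 1]
            assert matrix == pytest.approx(closed, abs=1e-12)

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(ValueError):
            cd.partial_correlation(0.3, 1.0, 0.2)

    def test_confounding_identity_in_simulation(self):
        r = np.random.default_rng(2)
        n = 2000
        c = r.standard_normal(n)
        a = 0.8 * c + r.standard_normal(n)
        b = 0.6 * c + r.standard_normal(n)
        marginal = np.corrcoef(a, b)[0, 1]
        expected = 0.48 / (np.sqrt(1.64) * np.sqrt(1.36))
        assert marginal == pytest.approx(expected, abs=0.06)
        assert abs(partial_corr_xy(a, b, c)) < 0.05

    def test_conditioning_on_independent_covariate_is_nearly_neutral(self):
        r = np.random.default_rng(3)
        n = 1000
        a, b, c = r.standard_normal((3, n))
        assert abs(
            partial_corr_xy(a, b, c) - np.corrcoef(a, b)[0, 1]
        ) < 2 / np.sqrt(n)


class TestResidualize:
    def test_removes_linear_covariate_effect(self):
        r = np.random.default_rng(4)
        x = r.standard_normal(500)
        y = 2.0 + 3.0 * x + r.standard_normal(500)
        res = residualize(y, x)
        assert abs(np.corrcoef(res, x)[0, 1]) < 1e-10
        assert abs(res.mean()) < 1e-10


class TestSpeciesPathwayAssociation:
    def _frames(self, n=200, seed=5):
        r = np.random.default_rng(seed)
        meta = pd.DataFrame(
            {
                "sample": [f"S{i}" for i in range(n)],
                "age": r.uniform(20, 70, n),
                "sex": r.integers(0, 2, n),
                "read_depth": r.integers(10_000, 50_000, n),
            }
        ).set_index("sample", drop=False)
        sp = r.lognormal(size=n)
        return meta, sp

    def test_monotone_transform_gives_unit_rho(self):
        meta, sp = self._frames()
        species = pd.DataFrame([sp], index=["s__a"], columns=meta.index)
        pathways = pd.DataFrame([np.log1p(sp)], index=["PWY-1"], columns=meta.index)
        # zero covariate effect: residual ranks are preserved
        out = cd.species_pathway_association(
            species, pathways, meta, covariates=(), n_perm=30, seed=6
        )
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_depth_mediated_association_removed(self):
        r = np.random.default_rng(7)
        n = 400
        depth = r.uniform(1e4, 1e5, n)
        meta = pd.DataFrame(
            {
                "sample": [f"S{i}" for i in range(n)],
                "age": r.uniform(20, 70, n),
                "sex": r.integers(0, 2, n),
                "read_depth": depth,
            }
        ).set_index("sample", drop=False)
        sp = 2e-4 * depth + r.standard_normal(n)
        pw = 1e-4 * depth + r.standard_normal(n)
        species = pd.DataFrame([sp], index=["s__a"], columns=meta.index)
        pathways = pd.DataFrame([pw], index=["PWY-1"], columns=meta.index)
        raw = cd.species_pathway_association(
            species, pathways, meta, covariates=(), n_perm=30, seed=8
        )
        adj = cd.species_pathway_association(
            species, pathways, meta, n_perm=30, seed=8
        )
        assert abs(adj["rho"].iloc[0]) < abs(raw["rho"].iloc[0])
        assert abs(adj["rho"].iloc[0]) < 0.1

    def test_null_pairs_uncorrelated(self):
        meta, _ = self._frames(n=500, seed=9)
        r = np.random.default_rng(10)
        species = pd.DataFrame(
            r.lognormal(size=(3, 500)), index=["s__a", "s__b", "s__c"],
            columns=meta.index,
        )
        pathways = pd.DataFrame(
            r.lognormal(size=(2, 500)), index=["P1", "P2"], columns=meta.index
        )
        out = cd.species_pathway_association(species, pathways, meta, n_perm=40, seed=11)
        assert (out["rho"].abs() < 0.1).mean() >= 0.95


class TestSpeciesContribution:
    def test_share_arithmetic_and_top_contributor(self):
        samples = ["S1", "S2"]
        community = pd.DataFrame([[120.0, 80.0]], index=["PWY-1"], columns=samples)
        strat = pd.DataFrame(
            [[30.0, 20.0], [90.0, 60.0]],
            index=["PWY-1|g__A.s__a", "PWY-1|g__B.s__b"],
            columns=samples,
        )
        out = cd.species_contribution(community, strat)
        a = out[out["species"] == "g__A.s__a"].iloc[0]
        b = out[out["species"] == "g__B.s__b"].iloc[0]
        assert a["mean_share"] == pytest.approx(0.25)
        assert b["mean_share"] == pytest.approx(0.75)
        assert b["top_contributor"] and not a["top_contributor"]

    def test_single_contributor_has_share_one(self):
        community = pd.DataFrame([[50.0]], index=["PWY-1"], columns=["S1"])
        strat = pd.DataFrame([[50.0]], index=["PWY-1|g__A.s__a"], columns=["S1"])
        out = cd.species_contribution(community, strat)
        assert out["mean_share"].iloc[0] == pytest.approx(1.0)

    def test_shares_invariant_to_sample_rescaling(self):
        community = pd.DataFrame([[120.0, 60.0]], index=["P"], columns=["S1", "S2"])
        strat = pd.DataFrame([[30.0, 15.0]], index=["P|g__A.s__a"], columns=["S1", "S2"])
        out1 = cd.species_contribution(community, strat)
        out2 = cd.species_contribution(community * 7, strat * 7)
        assert out1["mean_share"].iloc[0] == pytest.approx(out2["mean_share"].iloc[0])

    def test_inconsistent_stratified_rejected(self):
        community = pd.DataFrame([[10.0]], index=["P"], columns=["S1"])
        strat = pd.DataFrame([[20.0]], index=["P|g__A.s__a"], columns=["S1"])
        with pytest.raises(ValueError, match="exceeds"):
            cd.species_contribution(community, strat)

    def test_between_cohort_share_difference_detected(self):
        r = np.random.default_rng(12)
        n = 60
        shares_a = np.clip(r.normal(0.10, 0.03, n), 0, 1)
        shares_b = np.clip(r.normal(0.20, 0.03, n), 0, 1)
        stat, p = contribution_shift_test(shares_a, shares_b)
        assert p < 1e-6
        assert shares_a.mean() < shares_b.mean()


class TestAdjustSpecificity:
    def test_unconfounded_calls_survive(self):
        cfg = {
            "cohorts": [{"name": c, "n": 300} for c in ("C1", "C2", "C3", "C4")],
            "p": 10,
            "n_edges": 0,
            "rho": 0.0,
            "depth": 20_000,
            "planted": [{"i": 0, "j": 1, "cohort": "C4", "rho": 0.8}],
        }
        study = cd.make_study(cfg, seed=41)
        res = cd.cross_cohort_analysis(
            {n: c.counts for n, c in study.items()}, n_perm=40, seed=42, n_inner=5
        )
        assert len(res.specific) >= 1
        adjusted = cd.adjust_specificity(study, res.specific)
        feats = study["C1"].truth.features
        row = adjusted[
            (adjusted["feature_i"] == feats[0]) & (adjusted["feature_j"] == feats[1])
        ]
        assert row["survives"].iloc[0]

    def test_empty_calls_give_empty_output(self):
        cfg = {
            "cohorts": [{"name": c, "n": 30} for c in ("C1", "C2", "C3", "C4")],
            "p": 8, "n_edges": 0, "rho": 0.0, "depth": 5000,
        }
        study = cd.make_study(cfg, seed=43)
        empty = pd.DataFrame(columns=["feature_i", "feature_j", "outlier_cohort"])
        out = cd.adjust_specificity(study, empty)
        assert len(out) == 0
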