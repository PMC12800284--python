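"""Eigenproteins, association models, BH FDR, ranking, baseline table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpnet.datasets import TRAITS, example_rank_table
from cpnet.eigenassoc import (
    associate,
    baseline_table,
    bh_fdr,
    compute_eigenprotein,
    rank_networks,
    score_rank_table,
)
from cpnet.netbuild import Subnetwork
from cpnet.synthio import CovariateTable, PhenotypeTable, ProteinPanel


def make_panel(levels, ids=None):
    n, p = levels.shape
    ids = ids or [f"A{j}" for j in range(p)]
    ann = pd.DataFrame(
        {"aptamer_id": ids, "gene": ids, "chrom": ["1"] * p, "tss": range(p)}
    )
    return ProteinPanel([f"S{i}" for i in range(n)], ids, np.asarray(levels, float), ann)


def make_covs(n, rng):
    return CovariateTable(pd.DataFrame(
        {"age": rng.normal(70, 5, n), "sex": rng.integers(0, 2, n).astype(float)},
        index=[f"S{i}" for i in range(n)],
    ))


class TestEigenprotein:
    def test_identical_columns_explain_everything(self, rng):
        x = rng.normal(0, 1, 500)
        panel = make_panel(np.column_stack([x, x]))
        eig = compute_eigenprotein(Subnetwork("A0", {"A1"}), panel)
        assert eig.variance_fraction == pytest.approx(1.0)
        assert eig.valid

    def test_independent_members_fall_below_threshold(self, rng):
        # ten independent standard normals: PC1 fraction ~ Marchenko-Pastur
        # scale (1 + sqrt(p/n))^2 / p ~ 0.12 < 0.15
        panel = make_panel(rng.normal(0, 1, (2000, 10)))
        eig = compute_eigenprotein(Subnetwork("A0", set(panel.aptamer_ids[1:])), panel)
        assert eig.variance_fraction < 0.15
        assert not eig.valid

    def test_variance_fraction_matches_eigendecomposition(self, rng):
        lv = rng.normal(0, 1, (300, 5)) @ rng.normal(0, 1, (5, 5))
        panel = make_panel(lv)
        eig = compute_eigenprotein(Subnetwork("A0", set(panel.aptamer_ids[1:])), panel)
        z = (lv - lv.mean(0)) / lv.std(0)
        w = np.linalg.eigvalsh(np.cov(z.T))
        assert eig.variance_fraction == pytest.approx(w[-1] / w.sum(), rel=1e-6)

    def test_sign_oriented_to_regulator(self, rng):
        x = rng.normal(0, 1, 400)
        panel = make_panel(np.column_stack([x, -x + 0.05 * rng.normal(0, 1, 400), -x]))
        eig = compute_eigenprotein(Subnetwork("A0", {"A1", "A2"}), panel)
        assert np.corrcoef(eig.scores, x)[0, 1] > 0

    def test_scores_standardized_and_stable_under_reordering(self, rng):
        lv = rng.normal(0, 1, (200, 4))
        lv[:, 1] = lv[:, 0] + 0.1 * rng.normal(0, 1, 200)
        panel = make_panel(lv)
        sub = Subnetwork("A0", {"A1", "A2", "A3"})
        eig = compute_eigenprotein(sub, panel)
        assert eig.scores.mean() == pytest.approx(0, abs=1e-10)
        assert eig.scores.std() == pytest.approx(1)
        perm = rng.permutation(200)
        panel2 = ProteinPanel(
            [panel.sample_ids[i] for i in perm], panel.aptamer_ids,
            panel.levels[perm], panel.annotation,
        )
        eig2 = compute_eigenprotein(sub, panel2)
        np.testing.assert_allclose(eig2.scores, eig.scores[perm], rtol=1e-8)

    def test_constant_members_raise(self):
        panel = make_panel(np.ones((50, 3)))
        with pytest.raises(ValueError):
            compute_eigenprotein(Subnetwork("A0", {"A1", "A2"}), panel)

    def test_validity_threshold_is_strict(self, rng):
        x = rng.normal(0, 1, 500)
        panel = make_panel(np.column_stack([x, x]))
        eig = compute_eigenprotein(
            Subnetwork("A0", {"A1"}), panel, variance_threshold=1.0
        )
        # variance fraction exactly 1.0 is NOT > 1.0
        assert eig.variance_fraction == pytest.approx(1.0)
        assert not eig.valid


def null_phenotypes(n, rng):
    t = rng.exponential(20, n)
    c = rng.uniform(0, 40, n)
    table = pd.DataFrame(
        {
            "qt": rng.normal(0, 1, n),
            "dz": rng.binomial(1, 0.3, n).astype(int),
            "time_inc": np.minimum(t, c),
            "event_inc": (t <= c).astype(int),
        },
        index=[f"S{i}" for i in range(n)],
    )
    return PhenotypeTable(table, {"qt": "continuous", "dz": "prevalent", "inc": "incident"})


class TestAssociate:
    def test_type_one_error_calibrated_for_all_models(self):
        n, reps, alpha = 300, 1000, 0.05
        rejections = {"qt": 0, "dz": 0, "inc": 0}
        for r in range(reps):
            rng = np.random.default_rng(r)
            x = rng.normal(0, 1, n)
            covs = make_covs(n, rng)
            ph = null_phenotypes(n, rng)
            for trait in rejections:
                res = associate(x, ph, trait, covs)
                rejections[trait] += res.p < alpha
        tol = 3 * np.sqrt(alpha * (1 - alpha) / reps)  # ~0.021
        for trait, k in rejections.items():
            assert abs(k / reps - alpha) < tol, (trait, k / reps)

    def test_cox_recovers_planted_log_hazard(self, rng):
        n = 5000
        x = rng.normal(0, 1, n)
        covs = make_covs(n, rng)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.3 * x)))
        c = rng.uniform(0, 60, n)
        table = pd.DataFrame(
            {"time_inc": np.minimum(t, c), "event_inc": (t <= c).astype(int)},
            index=[f"S{i}" for i in range(n)],
        )
        ph = PhenotypeTable(table, {"inc": "incident"})
        res = associate(x, ph, "inc", covs)
        assert res.model == "cox"
        assert abs(res.estimate - 0.3) < 3 * res.se

    def test_logistic_recovers_planted_log_odds(self, rng):
        n = 5000
        x = rng.normal(0, 1, n)
        covs = make_covs(n, rng)
        eta = -1.0 + 0.4 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        ph = PhenotypeTable(
            pd.DataFrame({"dz": y}, index=[f"S{i}" for i in range(n)]),
            {"dz": "prevalent"},
        )
        res = associate(x, ph, "dz", covs)
        assert res.model == "logistic"
        assert abs(res.estimate - 0.4) < 3 * res.se

    def test_linear_recovers_planted_slope(self, rng):
        n = 5000
        x = rng.normal(0, 1, n)
        covs = make_covs(n, rng)
        y = 0.25 * x + 0.02 * covs.age + rng.normal(0, 1, n)
        ph = PhenotypeTable(
            pd.DataFrame({"qt": y}, index=[f"S{i}" for i in range(n)]),
            {"qt": "continuous"},
        )
        res = associate(x, ph, "qt", covs)
        assert res.model == "linear"
        assert abs(res.estimate - 0.25) < 3 * res.se

    def test_constant_exposure_raises(self, rng):
        n = 100
        ph = null_phenotypes(n, rng)
        with pytest.raises(ValueError):
            associate(np.ones(n), ph, "qt", make_covs(n, rng))

    def test_separation_flagged_not_fatal(self, rng):
        n = 80
        x = np.concatenate([np.zeros(40), np.ones(40)])
        y = x.astype(int)  # complete separation
        ph = PhenotypeTable(
            pd.DataFrame({"dz": y}, index=[f"S{i}" for i in range(n)]),
            {"dz": "prevalent"},
        )
        res = associate(x + rng.normal(0, 1e-6, n), ph, "dz", make_covs(n, rng))
        assert (not res.converged) or res.se > 10  # flagged or wildly unstable


class TestBhFdr:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.all(bh_fdr(np.ones(10)) == 1.0)

    def test_monotone_in_p(self, rng):
        p = rng.random(200)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestRankNetworks:
    def make_results(self, sig_map, unit):
        rows = []
        for (name, trait), sig in sig_map.items():
            rows.append(
                {"unit": unit, "name": name, "trait": trait,
                 "model": "linear", "estimate": 0.1, "se": 0.01,
                 "p": 1e-8 if sig else 0.9, "converged": True, "note": ""}
            )
        return pd.DataFrame(rows)

    def test_sub_scores_and_total(self):
        traits = ["t1", "t2"]
        reg = self.make_results(
            {("N1", "t1"): True, ("N1", "t2"): True,
             ("N2", "t1"): False, ("N2", "t2"): False}, "regulator"
        )
        eig = self.make_results(
            {("N1", "t1"): True, ("N1", "t2"): False,
             ("N2", "t1"): False, ("N2", "t2"): False}, "eigenprotein"
        )
        ranks = rank_networks(reg, eig, {"N1": True, "N2": True}, traits, top_cut=3)
        by = {r.subnetwork: r for r in ranks}
        assert by["N1"].sub_scores == {"t1": 2, "t2": 1}
        assert by["N1"].total == 3 and by["N1"].top_ranked
        assert by["N2"].total == 0 and not by["N2"].top_ranked

    def test_bh_eigen_rule_variant(self):
        traits = ["t1"]
        reg = self.make_results({("N1", "t1"): False}, "regulator")
        eig = self.make_results({("N1", "t1"): True}, "eigenprotein")
        fixed = rank_networks(reg, eig, {"N1": True}, traits,
                              eigen_p_threshold=1e-12, eigen_rule="fixed")
        bh = rank_networks(reg, eig, {"N1": True}, traits, eigen_rule="bh")
        assert fixed[0].sub_scores == {"t1": 0}  # p=1e-8 above 1e-12 cut
        assert bh[0].sub_scores == {"t1": 1}
        with pytest.raises(ValueError):
            rank_networks(reg, eig, {"N1": True}, traits, eigen_rule="nope")

    def test_invalid_eigenprotein_contributes_zero(self):
        traits = ["t1"]
        reg = self.make_results({("N1", "t1"): False}, "regulator")
        eig = self.make_results({("N1", "t1"): True}, "eigenprotein")
        ranks = rank_networks(reg, eig, {"N1": False}, traits)
        assert ranks[0].sub_scores == {"t1": 0}

    def test_missing_trait_treated_as_nonsignificant(self):
        traits = ["t1", "t2"]
        reg = self.make_results({("N1", "t1"): True}, "regulator")
        eig = self.make_results({}, "eigenprotein")
        ranks = rank_networks(reg, eig, {"N1": True}, traits)
        assert ranks[0].sub_scores == {"t1": 1, "t2": 0}

    def test_total_equals_sub_score_sum_always(self):
        table = example_rank_table()
        scored = score_rank_table(table)
        assert (scored["total"] == table.sum(axis=1)).all()

    def test_published_worked_examples(self):
        scored = score_rank_table(example_rank_table())
        assert scored.loc["ITIH3", "total"] == 11
        assert scored.loc["KLKB1", "total"] == 7
        assert scored.loc["DDX39B", "total"] == 10
        assert scored["top_ranked"].sum() == 25

    def test_bad_sub_scores_raise(self):
        bad = pd.DataFrame({"t": [3]}, index=["N1"])
        with pytest.raises(ValueError):
            score_rank_table(bad)


class TestBaselineTable:
    def test_identical_groups_give_p_one(self, rng):
        x = rng.normal(0, 1, 200)
        var = pd.DataFrame({"v": np.concatenate([x, x]),
                            "b": np.concatenate([rng.binomial(1, 0.4, 200)] * 2)})
        group = np.concatenate([np.zeros(200), np.ones(200)]).astype(bool)
        out = baseline_table(var, group, categorical=["b"]).set_index("variable")
        assert out.loc["v", "p"] == pytest.approx(1.0)
        assert out.loc["b", "p"] == pytest.approx(1.0, abs=0.05)

    def test_t_test_power_matches_closed_form(self, rng):
        n, d, reps = 50, 0.6, 300
        hits = 0
        for r in range(reps):
            g = np.random.default_rng(r)
            var = pd.DataFrame({"v": np.concatenate([g.normal(0, 1, n), g.normal(d, 1, n)])})
            group = np.concatenate([np.zeros(n), np.ones(n)]).astype(bool)
            p = baseline_table(var, group)["p"].iloc[0]
            hits += p < 0.05
        ncp = d / np.sqrt(2 / n)
        power = stats.norm.sf(stats.norm.isf(0.025) - ncp)  # normal approximation
        assert abs(hits / reps - power) < 0.1

    def test_chi_square_matches_hand_formula(self):
        # 2x2 table [[30, 20], [10, 40]] with continuity correction
        x = np.array([1] * 30 + [0] * 20 + [1] * 10 + [0] * 40)
        group = np.array([False] * 50 + [True] * 50)
        out = baseline_table(pd.DataFrame({"b": x}), group, categorical=["b"])
        obs = np.array([[20, 40], [30, 10]])
        exp = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        chi2 = ((np.abs(obs - exp) - 0.5) ** 2 / exp).sum()
        assert out["p"].iloc[0] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-6)

    def test_skewed_variable_uses_wilcoxon(self, rng):
        var = pd.DataFrame({"s": rng.exponential(1, 100)})
        group = rng.random(100) < 0.5
        out = baseline_table(var, group, skewed=["s"])
        assert out["kind"].iloc[0] == "skewed"
        assert "[" in out["group0"].iloc[0]  # median [IQR] format


class TestPipelineIntegration:
    def test_eigenproteins_and_ranking_run_on_fitted_network(self, default_run):
        model, res = default_run
        eig = res.eigenproteins()
        assert len(eig) == len([s for s in res.subnetworks if len(s.members) >= 2])
        for e in eig.values():
            assert 0 < e.variance_fraction <= 1
        ranks = res.rank()
        for r in ranks:
            assert r.total == sum(r.sub_scores.values())
            assert set(r.sub_scores) == set(model.phenotypes.trait_names())

    def test_trait_drivers_detected(self, default_run):
        # regulators planted as trait drivers should associate strongly
        model, res = default_run
        reg_res, _ = res.associate_traits()
        drivers = {
            (apt, trait)
            for trait, info in model.truth.phenotype_effects.items()
            for apt in info["effects"]
        }
        hits = reg_res[
            reg_res.apply(lambda r: (r["name"], r["trait"]) in drivers, axis=1)
        ]
        if len(hits):
            assert (hits["p"] < 0.05).mean() >= 0.5
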