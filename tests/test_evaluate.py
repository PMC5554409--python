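"""Concordance scoring, CV protocol, method comparison, hub bias, specificity."""

from math import comb, log

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import progeni as pg
from progeni.evaluate import fold_scores, make_partitions, top_network_genes
from progeni.prioritize import RANKING_COLUMNS


class TestConcordance:
    def test_perfect_and_reversed_ordering(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert pg.concordance_score(obs, obs) == 1.0
        assert pg.concordance_score(-obs, obs) == 0.0

    def test_constant_predictions_score_half(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert pg.concordance_score(np.zeros(3), obs) == 0.5

    def test_all_observed_tied_is_undefined(self):
        with pytest.raises(ValueError, match="concordance undefined"):
            pg.concordance_score(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    def test_invariant_to_monotone_transform_of_predictions(self):
        rng = np.random.default_rng(0)
        pred, obs = rng.random(30), rng.random(30)
        c = pg.concordance_score(pred, obs)
        assert pg.concordance_score(np.exp(5 * pred), obs) == c

    def test_random_predictions_center_at_half(self):
        rng = np.random.default_rng(42)
        cs = [
            pg.concordance_score(rng.random(1000), rng.random(1000))
            for _ in range(20)
        ]
        assert np.mean(cs) == pytest.approx(0.5, abs=0.02)

    def test_spci_endpoints_and_error_sd_requirement(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert pg.concordance_score(obs, obs, mode="spci", error_sd=0.5) == 1.0
        assert pg.concordance_score(-obs, obs, mode="spci", error_sd=0.5) == 0.0
        with pytest.raises(ValueError, match="error_sd"):
            pg.concordance_score(obs, obs, mode="spci")

    def test_spci_downweights_close_observed_pairs(self):
        # one discordant pair; penalty is milder when the observed gap is
        # within the noise scale
        obs = np.array([1.0, 1.1, 3.0])
        pred = np.array([1.1, 1.0, 3.0])  # swaps only the close pair
        hard = pg.concordance_score(pred, obs, mode="cindex")
        soft = pg.concordance_score(pred, obs, mode="spci", error_sd=1.0)
        assert soft > hard


class TestPif:
    def test_arithmetic(self):
        a = np.zeros(250)
        a[:140] = 1.0
        assert pg.pif(a, np.zeros(250)) == 56.0

    def test_ties_are_not_improvements(self):
        assert pg.pif(np.ones(5), np.ones(5)) == 0.0

    def test_uniform_improvement(self):
        assert pg.pif(np.arange(5) + 1.0, np.arange(5)) == 100.0


class TestCrossValidate:
    def test_partitions_are_disjoint_and_cover(self):
        parts = make_partitions(23, k=5, n_repeats=3, seed=0)
        for folds in parts:
            flat = np.concatenate(folds)
            assert len(flat) == 23
            assert len(np.unique(flat)) == 23

    def test_noiseless_linear_response_is_learned(self):
        net = pg.generate_network(80, seed=3)
        X, d, truth = pg.generate_dataset(
            net, n_samples=40, scenario="direct_drivers", noise_sd=0.0, seed=3
        )
        Xn = pg.normalize_expression(X, log2_first=False)
        res = pg.cross_validate(
            net, Xn, d, methods=("pcc_baseline",), n_genes=20, k=3,
            n_repeats=1, seed=0,
        )[
            "pcc_baseline"
        ]
        for fr in res:
            assert set(truth.driver_genes) <= set(fr.selected_genes)
        assert fold_scores(res).mean() > 0.9

    def test_gene_selection_ignores_test_responses(self, small_instance):
        net, Xn, d, _ = small_instance
        res = pg.cross_validate(
            net, Xn, d, methods=("pcc_baseline",), n_genes=30, k=4,
            n_repeats=1, seed=5,
        )["pcc_baseline"]
        for fr in res:
            shuffled = d.values.copy()
            perm_vals = shuffled.loc[fr.test_samples].to_numpy()[::-1]
            shuffled.loc[fr.test_samples] = perm_vals
            d2 = pg.ResponseVector(shuffled, treatment_id="t")
            res2 = pg.cross_validate(
                net, Xn, d2, methods=("pcc_baseline",), n_genes=30, k=4,
                n_repeats=1, seed=5,
            )["pcc_baseline"]
            other = next(
                fr2 for fr2 in res2 if fr2.fold == fr.fold and fr2.repeat == fr.repeat
            )
            assert other.selected_genes == fr.selected_genes

    def test_requesting_more_genes_than_available_warns(self, small_instance):
        net, Xn, d, _ = small_instance
        with pytest.warns(UserWarning, match="using all"):
            pg.cross_validate(
                net, Xn, d, methods=("pcc_baseline",), n_genes=10_000, k=3,
                n_repeats=1, seed=0,
            )


class TestCompareMethods:
    def test_identical_scores_give_overall_p_one(self):
        scores = {
            f"t{i}": {"a": np.full(10, 0.6), "b": np.full(10, 0.6)} for i in range(3)
        }
        res = pg.compare_methods(scores, "a", "b")
        assert res.overall_p == 1.0
        assert (res.per_treatment["pif"] == 0.0).all()

    def test_uniform_small_improvement_is_significant(self):
        rng = np.random.default_rng(0)
        scores = {}
        for i in range(24):
            b = 0.5 + 0.1 * rng.random(10)
            scores[f"t{i}"] = {"a": b + 0.01, "b": b}
        res = pg.compare_methods(scores, "a", "b")
        assert res.overall_p < 0.001
        assert (res.per_treatment["pif"] == 100.0).all()

    def test_fdr_column_is_bh_adjusted(self):
        rng = np.random.default_rng(1)
        scores = {
            f"t{i}": {"a": rng.random(12), "b": rng.random(12)} for i in range(5)
        }
        res = pg.compare_methods(scores, "a", "b")
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(
            res.per_treatment["p_value"].to_numpy(), method="fdr_bh"
        )[1]
        assert np.allclose(res.per_treatment["fdr"].to_numpy(), expected)

    def test_single_treatment_rejected_for_overall_test(self):
        with pytest.raises(ValueError, match="2 treatments"):
            pg.compare_methods(
                {"t": {"a": np.ones(4), "b": np.zeros(4)}}, "a", "b"
            )


def ranking_of(genes):
    k = len(genes)
    return pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "gene_id": list(genes),
            "score": np.linspace(1, 0, k),
            "abs_pcc": np.nan,
            "is_rcg": False,
            "off_network": False,
        }
    )[RANKING_COLUMNS]


class TestHubBias:
    @staticmethod
    def exhaustive_upper_tail(N, K, n, k):
        """P(overlap >= k) when drawing n of N with K marked, by enumeration."""
        return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / comb(N, n)

    def test_small_case_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        n = 20
        genes = [f"g{i:02d}" for i in range(n)]
        A = np.zeros((n, n))
        for i in range(n - 1):  # chain plus extra edges onto the first five
            A[i, i + 1] = A[i + 1, i] = 0.1
        for j in range(5, 17):
            A[j % 5, j] = A[j, j % 5] = 1.0
        net = pg.GeneNetwork(node_ids=genes, adjacency=A)
        deg = pd.Series(net.weighted_degree(), index=genes)
        hubs = set(deg.sort_values(ascending=False).head(5).index)
        top = list(sorted(hubs))[:2] + [g for g in genes if g not in hubs][:3]
        overlap, p = pg.hub_bias(ranking_of(top + [g for g in genes if g not in top]),
                                 net, n_top=5, n_hubs=5)
        assert overlap == 2
        assert p == pytest.approx(self.exhaustive_upper_tail(20, 5, 5, 2), rel=1e-12)

    def test_full_containment_and_disjoint_extremes(self):
        net = pg.generate_network(100, seed=1)
        deg = pd.Series(net.weighted_degree(), index=net.node_ids)
        order = list(deg.sort_values(ascending=False).index)
        overlap, p = pg.hub_bias(ranking_of(order), net, n_top=10, n_hubs=10)
        assert overlap == 10 and p < 1e-10
        overlap, p = pg.hub_bias(ranking_of(order[::-1]), net, n_top=10, n_hubs=10)
        assert overlap == 0 and p == pytest.approx(1.0)


class TestDrugSpecificity:
    def test_duplicated_treatment_shares_the_top_ranks(self):
        net = pg.generate_network(200, seed=2)
        X, resp, _ = pg.generate_multi_treatment(
            net, n_samples=60, n_treatments=2, seed=2
        )
        Xn = pg.normalize_expression(X, log2_first=False)
        resp["drug0_copy"] = pg.ResponseVector(
            resp["drug0"].values.copy(), treatment_id="drug0_copy"
        )
        res = pg.drug_specificity(
            net, Xn, resp, method="pcc_baseline", n_repeats=4, n_top=40, seed=0
        )
        assert res.per_treatment.loc["drug0", "rank"] <= 2
        assert res.per_treatment.loc["drug0_copy", "rank"] <= 2

    def test_fisher_statistic_closed_form(self):
        net = pg.generate_network(200, seed=4)
        X, resp, _ = pg.generate_multi_treatment(
            net, n_samples=60, n_treatments=3, seed=4
        )
        Xn = pg.normalize_expression(X, log2_first=False)
        res = pg.drug_specificity(
            net, Xn, resp, method="pcc_baseline", n_repeats=3, n_top=40, seed=1
        )
        expected = -2.0 * sum(log(p) for p in res.per_treatment["p_value"])
        assert res.fisher_statistic == pytest.approx(expected)
        assert res.fisher_p == pytest.approx(
            stats.chi2.sf(expected, df=2 * 3), rel=1e-12
        )

    def test_top_network_genes_respects_off_network_flag(self):
        rk = ranking_of(["a", "b", "c"])
        rk.loc[0, "off_network"] = True
        assert top_network_genes(rk, 2) == {"b", "c"}
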