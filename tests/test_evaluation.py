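"""Metrics, statistical tests and validation tasks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from midas.evaluation import (
    NullDistribution,
    compare_roc,
    deg_recovery_test,
    empirical_p,
    kruskal_wallis,
    mann_whitney_u,
    phase_ranking_test,
    ranked_deg_correlation,
    roc_auc,
    spearman,
    timesliced_test,
    wilcoxon_signed_rank_exact,
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 0, 0, 0, 0]) == 0.5

    def test_pairwise_enumeration_example(self):
        # positives {0.8, 0.3}, negatives {0.5, 0.1}: 3 of 4 pairs won
        assert roc_auc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_matches_pairwise_count_oracle(self, rng):
        scores = rng.random(60)
        scores[rng.integers(0, 60, 10)] = 0.5  # inject ties
        labels = (rng.random(60) < 0.3).astype(int)
        if labels.sum() in (0, 60):
            labels[:5] = [1, 1, 0, 0, 0]
        wins = halves = total = 0
        for s_p in scores[labels == 1]:
            for s_n in scores[labels == 0]:
                total += 1
                wins += s_p > s_n
                halves += s_p == s_n
        assert roc_auc(scores, labels) == pytest.approx((wins + 0.5 * halves) / total)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(100)
        labels = (rng.random(100) < 0.4).astype(int)
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_complement_invariant(self, rng):
        scores = rng.random(50)
        labels = np.array([1] * 10 + [0] * 40)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestRocAucProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=40),
        split=st.integers(1, 3),
    )
    @settings(max_examples=50, derandomize=True)
    def test_bounds_and_complement(self, scores, split):
        n = len(scores)
        labels = np.array([1] * split + [0] * (n - split))
        auc = roc_auc(scores, labels)
        assert 0.0 <= auc <= 1.0
        assert auc + roc_auc(-np.asarray(scores), labels) == pytest.approx(1.0)


class TestCompareRoc:
    def test_identical_curves_p_one(self):
        scores = np.linspace(0, 1, 40)
        labels = (scores > 0.6).astype(int)
        with pytest.warns(UserWarning, match="degenerate"):
            assert compare_roc(scores, scores, labels) == 1.0

    def test_separating_vs_random_significant(self, rng):
        labels = np.array([1] * 60 + [0] * 140)
        good = labels + rng.normal(0, 0.1, 200)
        random = rng.random(200)
        assert compare_roc(good, random, labels, method="delong") < 0.01

    def test_bootstrap_deterministic_per_seed(self, rng):
        labels = np.array([1] * 30 + [0] * 70)
        a, b = rng.random(100), rng.random(100)
        p1 = compare_roc(a, b, labels, method="bootstrap", n_boot=200, seed=5)
        p2 = compare_roc(a, b, labels, method="bootstrap", n_boot=200, seed=5)
        assert p1 == p2

    def test_delong_and_bootstrap_agree_roughly(self, rng):
        labels = np.array([1] * 50 + [0] * 150)
        a = labels + rng.normal(0, 0.5, 200)
        b = labels + rng.normal(0, 1.5, 200)
        pd_ = compare_roc(a, b, labels, method="delong")
        pb = compare_roc(a, b, labels, method="bootstrap", n_boot=500, seed=0)
        assert (pd_ < 0.05) == (pb < 0.05)


class TestEmpiricalP:
    def test_direct_count(self):
        assert empirical_p(5, np.arange(1, 11)) == 0.6  # 6 of 10 draws >= 5

    def test_more_extreme_than_all_draws(self):
        assert empirical_p(99, np.random.default_rng(0).random(1000)) == 0.0

    def test_absolute_observed_raw_draws(self):
        # the observed value enters as |observed| but the null draws enter
        # raw: of {−6, 4, 5} only 5 is >= |−5|
        assert empirical_p(-5, np.array([-6.0, 4.0, 5.0])) == pytest.approx(1 / 3)

    def test_add_one_correction(self):
        assert empirical_p(99, np.zeros(9), add_one=True) == pytest.approx(0.1)

    def test_monotone_non_increasing_in_observed(self, rng):
        draws = NullDistribution(rng.standard_normal(500), "sim")
        ps = [empirical_p(obs, draws) for obs in np.linspace(0, 3, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestRankTests:
    def test_identical_groups(self):
        x = list(range(10))
        _, p = mann_whitney_u(x, x)
        assert p > 0.9

    def test_spearman_perfect(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, 3 * x + 1)
        assert rho == pytest.approx(1.0)

    def test_spearman_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))

    def test_kruskal_requires_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])

    def test_mann_whitney_matches_exact_permutation_oracle(self, rng):
        x = list(rng.random(5))
        y = list(rng.random(4))
        _, p_approx = mann_whitney_u(x, y)
        # exact oracle: enumerate all assignments of the pooled sample
        pooled = x + y
        n_x = len(x)
        obs_u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), n_x):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u = stats.mannwhitneyu(xs, ys, alternative="two-sided").statistic
            mu = n_x * len(ys) / 2
            count += abs(u - mu) >= abs(obs_u - mu) - 1e-12
            total += 1
        assert p_approx == pytest.approx(count / total, abs=0.12)


class TestWilcoxonExact:
    @pytest.mark.parametrize(
        "w,expected",
        [(0, 2 / 256), (1, 4 / 256), (3, 10 / 256)],
    )
    def test_exact_enumeration_n8(self, w, expected):
        # build 8 untied differences whose positive ranks sum to w
        mags = np.arange(1.0, 9.0)
        signs = -np.ones(8)
        if w:  # make the ranks summing to w positive
            parts = {1: [1], 3: [3]}[w] if w in (1, 3) else []
            for r in parts:
                signs[r - 1] = 1
        d = signs * mags
        w_got, p = wilcoxon_signed_rank_exact(d)
        assert w_got == w
        assert p == pytest.approx(expected)

    def test_matches_scipy_exact_oracle(self, rng):
        d = rng.standard_normal(10)
        while len(np.unique(np.abs(d))) < 10:
            d = rng.standard_normal(10)
        _, p = wilcoxon_signed_rank_exact(d)
        p_scipy = stats.wilcoxon(d, alternative="two-sided", mode="exact").pvalue
        assert p == pytest.approx(p_scipy)

    def test_distribution_sums_to_two_to_n(self):
        # the internal convolution is asserted; exercise the tied path too
        _, p = wilcoxon_signed_rank_exact([1.0, -1.0, 2.0, -3.0])
        assert 0 < p <= 1

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_exact([0.0, 0.0])


class TestTimesliced:
    def _preds(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:03d}" for i in range(n)]
        return pd.Series(rng.random(n), index=genes), genes

    def test_top_genes_give_zero_p(self):
        preds, genes = self._preds()
        top = list(preds.sort_values(ascending=False).index[:10])
        res = timesliced_test(preds, top, n_random=200, seed=1)
        assert res["empirical_p"] == 0.0

    def test_constant_scores_give_p_one(self):
        genes = [f"G{i}" for i in range(50)]
        preds = pd.Series(np.ones(50), index=genes)
        res = timesliced_test(preds, genes[:5], n_random=100, seed=0)
        assert res["empirical_p"] == 1.0

    def test_planted_inflation_detected(self, rng):
        genes = [f"G{i:03d}" for i in range(300)]
        scores = rng.random(300)
        ts = list(rng.choice(genes, 20, replace=False))
        preds = pd.Series(scores, index=genes)
        preds.loc[ts] += 0.5
        res = timesliced_test(preds, ts, n_random=500, seed=3)
        assert res["empirical_p"] < 0.05
        assert res["mannwhitney_p"] < 0.05
        assert res["null"].n == 500

    def test_unscored_timesliced_gene_errors(self):
        preds, _ = self._preds()
        with pytest.raises(ValueError, match="not scored"):
            timesliced_test(preds, ["NOPE"], n_random=10)


class TestPhaseRanking:
    def test_separated_groups_significant(self, rng):
        genes = [f"G{i}" for i in range(60)]
        scores = np.concatenate([
            rng.normal(0.9, 0.02, 15),  # approved
            rng.normal(0.6, 0.02, 15),  # development
            rng.normal(0.3, 0.02, 30),  # non-target
        ])
        phases = {g: "approved" for g in genes[:15]}
        phases.update({g: "phase II" for g in genes[15:30]})
        res = phase_ranking_test(pd.Series(scores, index=genes), phases)
        assert res["mannwhitney_approved_vs_dev_p"] < 0.05
        assert res["kruskal_p"] < 0.05
        assert res["groups"]["approved"]["mean"] > res["groups"]["in development"]["mean"]

    def test_single_group_errors(self):
        preds = pd.Series([0.1, 0.2], index=["A", "B"])
        with pytest.raises(ValueError, match="two non-empty"):
            phase_ranking_test(preds, {})

    def test_type_one_calibration(self, rng):
        # identical distributions -> Kruskal-Wallis p approximately uniform
        ps = []
        genes = [f"G{i}" for i in range(90)]
        phases = {g: "approved" for g in genes[:30]}
        phases.update({g: "phase I" for g in genes[30:60]})
        for _ in range(100):
            preds = pd.Series(rng.random(90), index=genes)
            ps.append(phase_ranking_test(preds, phases)["kruskal_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDegRecovery:
    def _degs(self, n, rng, frac=0.3):
        genes = [f"G{i:04d}" for i in range(n)]
        padj = np.where(rng.random(n) < frac, rng.random(n) * 0.05,
                        0.05 + rng.random(n) * 0.95)
        return pd.DataFrame(
            {"stat": rng.standard_normal(n), "padj": padj,
             "baseMean": np.exp(rng.normal(3, 1.5, n))},
            index=genes,
        ), genes

    def test_exact_overlap_when_predictions_are_degs(self, rng):
        degs, genes = self._degs(400, rng)
        deg_genes = list(degs.index[degs["padj"] < 0.05])
        scores = pd.Series(0.0, index=genes)
        scores.loc[deg_genes] = 1.0
        res = deg_recovery_test(scores, degs, top_n=len(deg_genes),
                                n_random=50, seed=0)
        assert res["overlap"] == len(deg_genes)

    def test_planted_signal_detected(self, rng):
        degs, genes = self._degs(600, rng)
        # predictions correlated with |Wald|: DEGs score higher
        scores = pd.Series(rng.random(600) * 0.2, index=genes)
        scores[degs["padj"] < 0.05] += 0.7
        res = deg_recovery_test(scores, degs, top_n=100, n_random=300, seed=1)
        assert res["empirical_p"] < 0.05


class TestRankedDegCorrelation:
    def test_bin_count(self, rng):
        genes = [f"G{i:04d}" for i in range(1200)]
        degs = pd.DataFrame({"stat": rng.standard_normal(1200)}, index=genes)
        preds = pd.Series(rng.random(1200), index=genes)
        out = ranked_deg_correlation(preds, degs, top=1000, bin_size=200)
        assert len(out) == 5

    def test_monotone_predictions_give_rho_one(self, rng):
        genes = [f"G{i:04d}" for i in range(600)]
        stat = rng.standard_normal(600)
        degs = pd.DataFrame({"stat": stat}, index=genes)
        preds = pd.Series(stats.rankdata(stat) / 600.0, index=genes)
        out = ranked_deg_correlation(preds, degs, top=600, bin_size=200)
        assert np.allclose(out["rho"], 1.0)

    def test_independent_predictions_average_to_zero(self, rng):
        genes = [f"G{i:04d}" for i in range(400)]
        degs = pd.DataFrame({"stat": rng.standard_normal(400)}, index=genes)
        rhos = []
        for _ in range(30):
            preds = pd.Series(rng.random(400), index=genes)
            out = ranked_deg_correlation(preds, degs, top=400, bin_size=200)
            rhos.extend(out["rho"])
        assert abs(np.mean(rhos)) < 0.05
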