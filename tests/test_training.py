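"""Positive-unlabelled protocol: splitting, CV, undersampling, fold
training, bagging, tuning and shortlisting."""

import numpy as np
import pandas as pd
import pytest

from midas import GINConfig
from midas.evaluation import roc_auc
from midas.gin import GINModel
from midas.graphio import LabelSet
from midas.training import (
    FoldModel,
    FoldModelSet,
    PredictionTable,
    bag_predictions,
    make_cv_plan,
    outer_split,
    shortlist,
    train_gin,
    tune,
    undersample,
)


def label_set(genes, n_pos, rng=None):
    rng = rng or np.random.default_rng(0)
    pos = set(rng.choice(genes, size=n_pos, replace=False))
    return LabelSet(positives=pos)


class TestOuterSplit:
    def test_sizes_and_stratification(self, rng):
        genes = [f"G{i:04d}" for i in range(1000)]
        labels = label_set(genes, 80, rng)
        plan = outer_split(genes, labels, seed=1)
        assert set(plan.train) | set(plan.held_out) == set(genes)
        assert not set(plan.train) & set(plan.held_out)
        assert abs(len(plan.held_out) - 250) <= 10
        # positive fraction within +/-20% relative of the global 8%
        frac_held = sum(g in labels.positives for g in plan.held_out) / len(plan.held_out)
        assert 0.8 * 0.08 <= frac_held <= 1.2 * 0.08

    def test_small_example_stratified(self):
        genes = [f"G{i}" for i in range(100)]
        labels = label_set(genes, 8)
        plan = outer_split(genes, labels, seed=3)
        held_pos = sum(g in labels.positives for g in plan.held_out)
        assert 1 <= held_pos <= 3  # 2 +/- 1

    def test_deterministic_per_seed(self):
        genes = [f"G{i}" for i in range(200)]
        labels = label_set(genes, 20)
        assert outer_split(genes, labels, seed=5) == outer_split(genes, labels, seed=5)

    def test_constant_missingness_column_dropped_with_warning(self):
        genes = [f"G{i}" for i in range(100)]
        labels = label_set(genes, 10)
        miss = pd.DataFrame({"f": np.zeros(100, dtype=int)}, index=genes)
        with pytest.warns(UserWarning, match="constant stratification"):
            outer_split(genes, labels, missingness=miss, seed=0)

    def test_missingness_columns_balanced(self, rng):
        genes = [f"G{i:04d}" for i in range(800)]
        labels = label_set(genes, 60, rng)
        miss = pd.DataFrame({"f": (rng.random(800) < 0.2).astype(int)}, index=genes)
        plan = outer_split(genes, labels, missingness=miss, seed=2)
        f_train = miss.loc[list(plan.train), "f"].mean()
        f_held = miss.loc[list(plan.held_out), "f"].mean()
        assert abs(f_train - f_held) < 0.05


class TestCVPlan:
    def test_fold_sizes_and_membership(self):
        genes = [f"G{i:04d}" for i in range(1000)]
        labels = label_set(genes, 100)
        plan = make_cv_plan(genes, labels, repeats=10, folds=10, seed=0)
        for r in range(10):
            folds = [set(plan.test_fold(r, f)) for f in range(10)]
            assert all(len(f) == 100 for f in folds)
            covered = set().union(*folds)
            assert covered == set(genes)
        # a gene appears in exactly one test fold per repeat, ten overall
        g = genes[17]
        appearances = sum(g in plan.test_fold(r, f)
                          for r in range(10) for f in range(10))
        assert appearances == 10

    def test_too_few_genes_errors(self):
        genes = [f"G{i}" for i in range(5)]
        with pytest.raises(ValueError):
            make_cv_plan(genes, label_set(genes, 2), folds=10)

    def test_few_positives_reduces_folds(self):
        genes = [f"G{i}" for i in range(100)]
        labels = label_set(genes, 4)
        with pytest.warns(UserWarning, match="reducing folds"):
            plan = make_cv_plan(genes, labels, repeats=2, folds=10)
        assert plan.folds == 4


class TestUndersample:
    def test_paper_scale_counts(self, rng):
        genes = [f"G{i:05d}" for i in range(260 + 11659)]
        labels = label_set(genes, 260, rng)
        balanced = undersample(genes, labels, seed=0)
        assert len(balanced) == 520
        assert labels.positives <= set(balanced)  # never drops a positive

    def test_balanced_input_unchanged(self):
        genes = [f"G{i}" for i in range(10)]
        labels = label_set(genes, 5)
        with pytest.warns(UserWarning, match="keeping all"):
            assert set(undersample(genes, labels)) == set(genes)

    def test_deterministic(self):
        genes = [f"G{i}" for i in range(100)]
        labels = label_set(genes, 10)
        assert undersample(genes, labels, seed=9) == undersample(genes, labels, seed=9)

    @pytest.mark.parametrize("seed", range(4))
    def test_positives_always_kept(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(150)]
        labels = label_set(genes, int(rng.integers(5, 40)), rng)
        balanced = undersample(genes, labels, seed=seed)
        assert labels.positives <= set(balanced)


class TestTrainGin:
    def test_zero_epochs_is_initialization(self, small_bundle):
        graph = small_bundle.graph
        from midas.graphio import impute

        table = impute(small_bundle.features, graph.nodes)
        x = table.reindex(graph.nodes).matrix()
        cfg = GINConfig(d_in=x.shape[1], epochs=0, seed=3)
        model = train_gin(cfg, graph, x, list(graph.nodes)[:100],
                          small_bundle.labels, seed=3)
        init = GINModel(model.config)
        np.testing.assert_allclose(
            model.predict_proba(graph, x), init.predict_proba(graph, x)
        )

    def test_fixed_seed_reproducible(self, small_bundle):
        from midas.graphio import impute

        graph = small_bundle.graph
        x = impute(small_bundle.features, graph.nodes).reindex(graph.nodes).matrix()
        cfg = GINConfig(d_in=x.shape[1], epochs=5)
        genes = list(graph.nodes)[:120]
        m1 = train_gin(cfg, graph, x, genes, small_bundle.labels, seed=4)
        m2 = train_gin(cfg, graph, x, genes, small_bundle.labels, seed=4)
        np.testing.assert_array_equal(
            m1.predict_proba(graph, x), m2.predict_proba(graph, x)
        )

    def test_beats_label_shuffle_null(self, desk_results):
        fm = desk_results.fold_models[0]
        x = desk_results.features.matrix()
        probs = fm.model.predict_proba(desk_results.graph, x, genes=fm.test_genes)
        y = desk_results.labels.y(list(fm.test_genes))
        auc = roc_auc(probs, y)
        rng = np.random.default_rng(0)
        null = [roc_auc(probs, rng.permutation(y)) for _ in range(200)]
        assert auc > np.mean(null) + 3 * np.std(null)


class _ConstantModel:
    """Duck-typed stand-in emitting one constant probability per gene."""

    def __init__(self, value):
        self.value = value

    def predict_proba(self, graph, x, genes=None, **kw):
        n = len(genes) if genes is not None else graph.n_nodes
        return np.full(n, self.value)


def stub_fold_models(plan, train_genes):
    fms = FoldModelSet()
    v = 0.0
    for (r, f), test in sorted(plan.assignment.items()):
        v += 0.01
        fms.models.append(FoldModel(model=_ConstantModel(v), repeat=r, fold=f,
                                    train_genes=tuple(g for g in train_genes
                                                      if g not in set(test)),
                                    test_genes=tuple(test)))
    return fms


class TestBagging:
    def test_contributing_counts_ten_and_hundred(self):
        # the canonical 10x10 plan: 10 models per training gene, 100 for held-out
        genes = [f"G{i:04d}" for i in range(300)]
        labels = label_set(genes, 40)
        train, held = genes[:200], genes[200:]
        plan = make_cv_plan(train, labels, repeats=10, folds=10, seed=0)
        fms = stub_fold_models(plan, train)
        from midas.graphio import GeneGraph

        graph = GeneGraph(genes, [(genes[i], genes[i + 1]) for i in range(299)])
        preds = bag_predictions(fms, graph, np.zeros((300, 1)), genes, held)
        counts = preds.table["n_models"]
        assert (counts.loc[train] == 10).all()
        assert (counts.loc[held] == 100).all()

    def test_mean_equals_arithmetic_mean_oracle(self):
        genes = [f"G{i}" for i in range(40)]
        labels = label_set(genes, 8)
        plan = make_cv_plan(genes, labels, repeats=2, folds=4, seed=1)
        fms = stub_fold_models(plan, genes)
        from midas.graphio import GeneGraph

        graph = GeneGraph(genes, [(genes[i], genes[i + 1]) for i in range(39)])
        preds = bag_predictions(fms, graph, np.zeros((40, 1)), genes, held_out=[])
        for g in genes[:5]:
            eligible_vals = [0.01 * (i + 1) for i, fm in enumerate(fms)
                             if g in fm.test_genes]
            assert preds.scores[g] == pytest.approx(np.mean(eligible_vals))

    def test_ranks_are_permutation_with_lexicographic_ties(self):
        genes = ["B", "A", "C", "D"]
        per_model = np.array([[0.5, 0.5, 0.9, 0.1]])
        eligible = np.ones((1, 4), dtype=bool)
        table = PredictionTable(genes, per_model, eligible).table
        assert sorted(table["rank"]) == [1, 2, 3, 4]
        assert table.loc["C", "rank"] == 1
        # tie between A and B broken by identifier
        assert table.loc["A", "rank"] < table.loc["B", "rank"]

    def test_zero_eligible_models_errors(self):
        with pytest.raises(ValueError, match="zero models"):
            PredictionTable(["A"], np.array([[0.5]]), np.zeros((1, 1), dtype=bool))


class TestTune:
    def test_budget_one_returns_single_config(self):
        cfg, score = tune({"width": [4]}, None, np.zeros((10, 3)), None, None,
                          None, budget=1, seed=0, evaluator=lambda c: 0.7)
        assert cfg.width == 4 and score == 0.7

    def test_better_config_chosen(self):
        scores = {8: 0.6, 16: 0.9}
        cfg, _ = tune({"width": [8, 16]}, None, np.zeros((10, 3)), None, None,
                      None, budget=20, seed=0, evaluator=lambda c: scores[c.width])
        assert cfg.width == 16

    def test_monotone_incumbent(self):
        seen = []

        def evaluator(cfg):
            val = {4: 0.5, 8: 0.55, 16: 0.8}[cfg.width]
            seen.append(val)
            return val

        _, best = tune({"width": [4, 8, 16]}, None, np.zeros((5, 3)), None,
                       None, None, budget=10, seed=1, evaluator=evaluator)
        assert best == max(seen)

    def test_all_failures_raise(self):
        def evaluator(cfg):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="trials failed"):
            tune({"width": [4]}, None, np.zeros((5, 3)), None, None, None,
                 budget=3, seed=0, evaluator=evaluator)


class TestShortlist:
    def _table(self, order):
        per_model = np.array([[1.0 - 0.01 * i for i in range(len(order))]])
        return PredictionTable(order, per_model, np.ones((1, len(order)), dtype=bool))

    def test_positives_removed_order_preserved(self):
        preds = self._table(["P1", "A", "P2", "B", "C"])
        labels = LabelSet(positives={"P1", "P2"})
        assert shortlist(preds, labels, top_n=5) == ["A", "B", "C"]

    def test_no_positives_unchanged(self):
        preds = self._table(["A", "B", "C"])
        assert shortlist(preds, LabelSet(positives={"Z"}), top_n=3) == ["A", "B", "C"]


class TestEndToEnd:
    def test_pipeline_reproducible(self, small_bundle):
        from midas import TargetDiscoveryModel

        cfg = GINConfig(d_in=20, epochs=5)
        model = TargetDiscoveryModel.from_synthetic(small_bundle, config=cfg)
        r1 = model.fit(seed=2, repeats=1, folds=3)
        r2 = model.fit(seed=2, repeats=1, folds=3)
        pd.testing.assert_frame_equal(r1.predictions.table, r2.predictions.table)

    def test_summary_mentions_key_quantities(self, small_results):
        text = small_results.summary()
        assert "held-out ROC-AUC" in text and "fold models" in text
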