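"""High-level modelling surface: a model object built from data whose
``fit`` returns a results object carrying estimates and diagnostics.

:class:`TargetDiscoveryModel` wraps the aligned graph / features / labels
triple; ``fit`` runs the full positive-unlabelled protocol (outer split,
train-statistic imputation, repeated stratified CV with undersampling, fold
training, out-of-fold bagging) and returns a
:class:`TargetDiscoveryResults` exposing the bagged prediction table, fold
diagnostics, the in-silico validation tasks and the permutation
interpretability procedures.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import evaluation, interpret, training
from .gin import GINConfig
from .graphio import (
    FeatureTable,
    GeneGraph,
    LabelSet,
    PathwaySet,
    align_to_graph,
    impute,
    load_edge_list,
    load_feature_table,
    load_gmt,
    load_labels,
)


class TargetDiscoveryModel:
    """Gene-level binary target classifier over an interaction graph.

    Parameters
    ----------
    graph
        Undirected gene-interaction network (message-passing substrate).
    features
        Node feature table; missing markers are allowed and will be imputed
        per-policy inside ``fit`` using training-partition statistics.
    labels
        Positive targets (closed-world negatives implied), phases and the
        time-sliced set.
    config
        GIN architecture / training hyperparameters; defaults are used when
        omitted (the input width is always inferred from the features).
    """

    def __init__(
        self,
        graph: GeneGraph,
        features: FeatureTable,
        labels: LabelSet,
        config: GINConfig | None = None,
        pathways: PathwaySet | None = None,
    ):
        features, labels, report = align_to_graph(features, labels, graph)
        if report["dropped"]:
            graph = graph.induced_subgraph(features.genes)
        self.graph = graph
        self.features = features
        self.labels = labels
        self.pathways = pathways
        self.alignment_report = report
        if config is None:
            config = GINConfig(d_in=features.n_features)
        else:
            config = replace(config, d_in=features.n_features)
        self.config = config

    @classmethod
    def from_files(
        cls,
        edges,
        features_tsv,
        specs_json,
        labels_tsv,
        timesliced=None,
        pathways_gmt=None,
        config: GINConfig | None = None,
        header: bool = False,
    ) -> "TargetDiscoveryModel":
        graph, _ = load_edge_list(edges, header=header)
        features = load_feature_table(features_tsv, specs_json)
        labels = load_labels(labels_tsv, timesliced=timesliced)
        pathways = load_gmt(pathways_gmt) if pathways_gmt is not None else None
        return cls(graph, features, labels, config=config, pathways=pathways)

    @classmethod
    def from_synthetic(cls, bundle, config: GINConfig | None = None) -> "TargetDiscoveryModel":
        return cls(bundle.graph, bundle.features, bundle.labels,
                   config=config, pathways=bundle.pathways)

    def fit(
        self,
        seed: int = 0,
        repeats: int = 10,
        folds: int = 10,
        test_fraction: float = 0.25,
        undersample_ratio: float = 1.0,
    ) -> "TargetDiscoveryResults":
        """Run the full protocol and return the fitted results."""
        missingness = self.features.missingness_indicators()
        split = training.outer_split(
            list(self.features.genes), self.labels, missingness,
            seed=seed, test_fraction=test_fraction,
        )
        imputed = impute(self.features, split.train, split.held_out)
        graph = self.graph
        if len(imputed.genes) < len(self.features.genes):  # true-exclude drops
            graph = graph.induced_subgraph(imputed.genes)
            split = training.SplitPlan(
                train=tuple(g for g in split.train if g in graph),
                held_out=tuple(g for g in split.held_out if g in graph),
            )
        imputed = imputed.reindex(graph.nodes)
        x = imputed.matrix()
        labels = self.labels.restrict(graph.nodes)
        cv = training.make_cv_plan(split.train, labels, repeats=repeats,
                                   folds=folds, seed=seed)
        fold_models = training.train_folds(
            self.config, graph, x, split.train, labels, cv,
            seed=seed, undersample_ratio=undersample_ratio,
        )
        predictions = training.bag_predictions(
            fold_models, graph, x, list(graph.nodes), split.held_out
        )
        return TargetDiscoveryResults(
            model=self, graph=graph, features=imputed, labels=labels,
            split=split, cv_plan=cv, fold_models=fold_models,
            predictions=predictions, seed=seed,
        )


class TargetDiscoveryResults:
    """Fitted protocol output: bagged predictions plus diagnostics.

    Validation tasks and permutation interpretability are methods here so a
    fitted object is self-contained.
    """

    def __init__(self, model, graph, features, labels, split, cv_plan,
                 fold_models, predictions, seed):
        self.model = model
        self.graph = graph
        self.features = features
        self.labels = labels
        self.split = split
        self.cv_plan = cv_plan
        self.fold_models = fold_models
        self.predictions = predictions
        self.seed = seed
        self._x = features.matrix()

    # -- diagnostics ---------------------------------------------------
    def fold_aucs(self) -> pd.DataFrame:
        """Per-fold-model training and test ROC-AUC."""
        rows = []
        for fm in self.fold_models:
            train_probs = fm.model.predict_proba(self.graph, self._x, genes=fm.train_genes)
            test_probs = fm.model.predict_proba(self.graph, self._x, genes=fm.test_genes)
            rows.append({
                "repeat": fm.repeat,
                "fold": fm.fold,
                "train_auc": evaluation.roc_auc(train_probs, self.labels.y(list(fm.train_genes))),
                "test_auc": evaluation.roc_auc(test_probs, self.labels.y(list(fm.test_genes))),
            })
        return pd.DataFrame(rows)

    def heldout_auc(self) -> float:
        """ROC-AUC of the bagged scores on the held-out partition."""
        held = list(self.split.held_out)
        scores = self.predictions.scores.loc[held]
        return evaluation.roc_auc(scores.to_numpy(), self.labels.y(held))

    def summary(self) -> str:
        aucs = self.fold_aucs()
        lines = [
            "Target discovery results",
            "=" * 60,
            f"genes                 {self.graph.n_nodes}",
            f"edges                 {self.graph.n_edges}",
            f"positives             {len(self.labels.positives & set(self.graph.nodes))}",
            f"train / held-out      {len(self.split.train)} / {len(self.split.held_out)}",
            f"fold models           {len(self.fold_models)} "
            f"({self.cv_plan.repeats}x{self.cv_plan.folds} CV)",
            f"CV test ROC-AUC       {aucs['test_auc'].mean():.3f} "
            f"+/- {aucs['test_auc'].std():.3f}",
            f"held-out ROC-AUC      {self.heldout_auc():.3f} (bagged)",
            "=" * 60,
        ]
        return "\n".join(lines)

    # -- candidate ranking --------------------------------------------
    def shortlist(self, top_n: int = 300) -> list[str]:
        """Top predictions with known positives removed."""
        return training.shortlist(self.predictions, self.labels, top_n=top_n)

    def to_tsv(self, path) -> None:
        self.predictions.table.to_csv(path, sep="\t")

    # -- in-silico validation -----------------------------------------
    def validate_timesliced(self, n_random: int = 1000, seed: int | None = None, **kw) -> dict:
        return evaluation.timesliced_test(
            self.predictions.scores, sorted(self.labels.timesliced),
            n_random=n_random, seed=self.seed if seed is None else seed, **kw,
        )

    def validate_phase_ranking(self, **kw) -> dict:
        return evaluation.phase_ranking_test(
            self.predictions.scores, self.labels.phases,
            timesliced=self.labels.timesliced, **kw,
        )

    def validate_deg_recovery(self, degs: pd.DataFrame, top_n: int = 200,
                              n_random: int = 1000, seed: int | None = None, **kw) -> dict:
        return evaluation.deg_recovery_test(
            self.predictions.scores, degs, top_n=top_n, n_random=n_random,
            seed=self.seed if seed is None else seed, **kw,
        )

    def deg_correlation(self, degs: pd.DataFrame, top: int = 1000,
                        bin_size: int = 200) -> pd.DataFrame:
        return evaluation.ranked_deg_correlation(
            self.predictions.scores, degs, top=top, bin_size=bin_size
        )

    # -- interpretability ---------------------------------------------
    def feature_importance(self, target: str, n_perm: int = 500,
                           eval_set: str = "cv-train", seed: int | None = None, **kw):
        return interpret.feature_importance(
            self.fold_models, self.graph, self.features, self.labels, target,
            n_perm=n_perm, eval_set=eval_set,
            seed=self.seed if seed is None else seed, split=self.split, **kw,
        )

    def recall_importance(self, target: str, specificity: float = 0.9,
                          n_perm: int = 500, eval_set: str = "cv-train",
                          seed: int | None = None, **kw):
        return interpret.recall_importance(
            self.fold_models, self.graph, self.features, self.labels, target,
            specificity=specificity, n_perm=n_perm, eval_set=eval_set,
            seed=self.seed if seed is None else seed, split=self.split, **kw,
        )

    def network_importance(self, n_perm: int = 500, seed: int | None = None, **kw) -> dict:
        return interpret.network_importance(
            self.fold_models, self.graph, self.features, self.labels,
            n_perm=n_perm, seed=self.seed if seed is None else seed, **kw,
        )

    def pathway_importance(self, target: str, pathways: PathwaySet | None = None,
                           n_perm: int = 100, seed: int | None = None,
                           model_index: int = 0, **kw):
        pw = pathways if pathways is not None else self.model.pathways
        if pw is None:
            raise ValueError("no pathway set supplied")
        return interpret.pathway_importance(
            self.fold_models[model_index].model, self.graph, self.features,
            pw, target, n_perm=n_perm,
            seed=self.seed if seed is None else seed, **kw,
        )
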