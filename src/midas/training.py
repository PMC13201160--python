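"""Positive-unlabelled training protocol.

Genes are split 75/25 into a training partition (where repeated
cross-validation runs) and a held-out partition, stratified by target
status and per-feature missingness.  Within the training partition a
10x-repeated stratified 10-fold CV plan is drawn; each fold model trains on
an undersampled (1:1) balance of positives and negatives and is bagged
out-of-fold: a gene's score averages only models whose CV training fold
excluded it — exactly 10 contributing models for training-partition genes
and all 100 for held-out genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._nn import Adam, sigmoid
from .evaluation import roc_auc
from .gin import GINConfig, GINModel, sampled_adjacency
from .graphio import FeatureTable, GeneGraph, LabelSet


@dataclass(frozen=True)
class SplitPlan:
    """Outer 75/25 train / held-out gene partition."""

    train: tuple[str, ...]
    held_out: tuple[str, ...]

    def __post_init__(self):
        if set(self.train) & set(self.held_out):
            raise ValueError("train and held-out partitions overlap")


@dataclass(frozen=True)
class CVPlan:
    """(repeat, fold) -> test-fold genes over the training partition."""

    repeats: int
    folds: int
    assignment: dict[tuple[int, int], tuple[str, ...]]

    def test_fold(self, repeat: int, fold: int) -> tuple[str, ...]:
        return self.assignment[(repeat, fold)]

    def train_fold_genes(self, repeat: int, fold: int, train_genes) -> list[str]:
        test = set(self.assignment[(repeat, fold)])
        return [g for g in train_genes if g not in test]


@dataclass
class FoldModel:
    model: GINModel
    repeat: int
    fold: int
    train_genes: tuple[str, ...]  # post-undersampling
    test_genes: tuple[str, ...]


@dataclass
class FoldModelSet:
    models: list[FoldModel] = field(default_factory=list)

    def __len__(self):
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]


class PredictionTable:
    """Per-gene bagged probabilities with out-of-fold bookkeeping.

    ``table`` has columns mean, n_models and rank (1 = highest mean, ties
    broken lexicographically by gene identifier); ``per_model`` holds the
    full model x gene probability matrix and ``eligible`` the boolean mask
    of models allowed to contribute to each gene.
    """

    def __init__(self, genes, per_model: np.ndarray, eligible: np.ndarray):
        self.genes = tuple(genes)
        self.per_model = per_model
        self.eligible = eligible
        if np.any(eligible.sum(axis=0) == 0):
            bad = [g for g, n in zip(self.genes, eligible.sum(axis=0)) if n == 0]
            raise ValueError(f"genes eligible for zero models: {bad[:5]}")
        with np.errstate(invalid="ignore"):
            means = np.where(eligible, per_model, np.nan)
            mean = np.nanmean(means, axis=0)
        df = pd.DataFrame(
            {"mean": mean, "n_models": eligible.sum(axis=0)},
            index=pd.Index(self.genes, name="gene"),
        )
        order = df.sort_values(["mean", "gene"], ascending=[False, True], kind="stable").index
        df.loc[order, "rank"] = np.arange(1, len(df) + 1)
        df["rank"] = df["rank"].astype(int)
        self.table = df

    @property
    def scores(self) -> pd.Series:
        return self.table["mean"]

    def gene_scores(self, gene: str) -> np.ndarray:
        j = self.genes.index(gene)
        return self.per_model[self.eligible[:, j], j]

    def ranked_genes(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


# ----------------------------------------------------------------------
# splitting


def _iterative_stratification(Y: np.ndarray, test_fraction: float, rng: np.random.Generator):
    """Greedy iterative stratification of a multilabel matrix into two sets.

    Follows the standard algorithm: repeatedly take the label with the
    fewest remaining examples and assign its examples to the side whose
    desired count for that label is largest (ties by overall remaining
    capacity, then at random)."""
    n, n_labels = Y.shape
    desired = np.array([(1 - test_fraction) * n, test_fraction * n])
    desired_label = np.stack(
        [(1 - test_fraction) * Y.sum(axis=0), test_fraction * Y.sum(axis=0)]
    )
    assignment = np.full(n, -1)
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        counts = Y[remaining].sum(axis=0)
        active = np.where(counts > 0)[0]
        if len(active) == 0:
            # label-free leftovers: fill by remaining capacity
            for i in np.where(remaining)[0]:
                side = int(np.argmax(desired + rng.random(2) * 1e-9))
                assignment[i] = side
                desired[side] -= 1
                remaining[i] = False
            break
        label = active[np.argmin(counts[active])]
        for i in np.where(remaining & (Y[:, label] == 1))[0]:
            gains = desired_label[:, label]
            best = np.where(gains == gains.max())[0]
            if len(best) > 1:
                caps = desired[best]
                best = best[caps == caps.max()]
            side = int(rng.choice(best))
            assignment[i] = side
            desired[side] -= 1
            desired_label[side] -= Y[i]
            remaining[i] = False
    return assignment


def outer_split(
    genes,
    labels: LabelSet,
    missingness: pd.DataFrame | None = None,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> SplitPlan:
    """75/25 multilabel-stratified shuffle split over target status and
    per-feature missingness indicator columns.

    Constant stratification columns are dropped with a warning.
    """
    genes = list(genes)
    y = labels.y(genes)
    if y.sum() < 2:
        raise ValueError("need at least 2 positives to stratify the outer split")
    cols = [y]
    if missingness is not None:
        for c in missingness.columns:
            col = missingness.loc[genes, c].to_numpy(dtype=int)
            if col.min() == col.max():
                warnings.warn(f"constant stratification column {c!r} dropped")
                continue
            cols.append(col)
    Y = np.stack(cols, axis=1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    assignment = np.empty(len(genes), dtype=int)
    assignment[perm] = _iterative_stratification(Y[perm], test_fraction, rng)
    train = tuple(g for g, a in zip(genes, assignment) if a == 0)
    held = tuple(g for g, a in zip(genes, assignment) if a == 1)
    return SplitPlan(train=train, held_out=held)


def make_cv_plan(
    train_genes, labels: LabelSet, repeats: int = 10, folds: int = 10, seed: int = 0
) -> CVPlan:
    """Repeated stratified k-fold partitions of the training genes."""
    train_genes = list(train_genes)
    if len(train_genes) < folds:
        raise ValueError(f"{len(train_genes)} genes cannot fill {folds} folds")
    y = labels.y(train_genes)
    if y.sum() < folds:
        new_folds = max(2, int(y.sum()))
        warnings.warn(
            f"only {y.sum()} positives in the training set; reducing folds "
            f"from {folds} to {new_folds}"
        )
        folds = new_folds
    assignment = {}
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(train_genes)), y)):
            assignment[(r, f)] = tuple(train_genes[i] for i in test_idx)
    return CVPlan(repeats=repeats, folds=folds, assignment=assignment)


def undersample(genes, labels: LabelSet, seed: int = 0, ratio: float = 1.0) -> list[str]:
    """Keep all positives; sample negatives without replacement down to
    ``ratio`` negatives per positive."""
    genes = list(genes)
    pos = [g for g in genes if g in labels.positives]
    neg = [g for g in genes if g not in labels.positives]
    if not pos or not neg:
        raise ValueError("undersampling needs both classes present")
    n_neg = int(round(ratio * len(pos)))
    if len(neg) <= n_neg:
        warnings.warn("fewer negatives than requested; keeping all")
        return genes
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(neg), size=n_neg, replace=False)
    kept = set(pos) | {neg[i] for i in picked}
    return [g for g in genes if g in kept]


# ----------------------------------------------------------------------
# fold training


def train_gin(
    config: GINConfig,
    graph: GeneGraph,
    x: np.ndarray,
    train_genes,
    labels: LabelSet,
    seed: int = 0,
) -> GINModel:
    """Full-batch training of one GIN with binary cross-entropy and Adam.

    The forward pass covers every node (message passing needs the whole
    graph); the loss is computed on ``train_genes`` only.  Neighbourhoods
    are resampled per layer per epoch when ``k_neighbours`` is finite.
    Deterministic on CPU for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    model = GINModel(replace(config, seed=int(rng.integers(2**31))))
    optim = Adam(model.layers(), lr=config.learning_rate)
    idx = np.array([graph.index(g) for g in train_genes])
    y = labels.y(list(train_genes)).astype(float)
    n = graph.n_nodes
    for _ in range(config.epochs):
        adjacencies = [
            sampled_adjacency(graph, config.k_neighbours, rng)
            for _ in range(config.n_gnn)
        ]
        logits = model.forward_logits(x, adjacencies, training=True, rng=rng)
        p = sigmoid(logits[idx])
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss {loss!r}; check feature scaling "
                f"and learning rate {config.learning_rate}"
            )
        dlogits = np.zeros(n)
        dlogits[idx] = (p - y) / len(idx)
        model.backward(dlogits)
        optim.step()
    return model


def train_folds(
    config: GINConfig,
    graph: GeneGraph,
    x: np.ndarray,
    train_genes,
    labels: LabelSet,
    cv: CVPlan,
    seed: int = 0,
    undersample_ratio: float = 1.0,
) -> FoldModelSet:
    """Train one model per (repeat, fold) on undersampled fold-train genes."""
    out = FoldModelSet()
    root = np.random.default_rng(seed)
    for (r, f), test_genes in sorted(cv.assignment.items()):
        fold_seed = int(root.integers(2**31))
        fold_train = cv.train_fold_genes(r, f, train_genes)
        balanced = undersample(fold_train, labels, seed=fold_seed, ratio=undersample_ratio)
        model = train_gin(config, graph, x, balanced, labels, seed=fold_seed)
        out.models.append(
            FoldModel(model=model, repeat=r, fold=f,
                      train_genes=tuple(balanced), test_genes=tuple(test_genes))
        )
    return out


def bag_predictions(
    fold_models: FoldModelSet,
    graph: GeneGraph,
    x: np.ndarray,
    genes,
    held_out,
) -> PredictionTable:
    """Out-of-fold bagging: a gene's mean uses only models whose CV training
    fold excluded it — the models holding it in their test fold for
    training-partition genes, every model for held-out genes."""
    genes = list(genes)
    held_out = set(held_out)
    n_models = len(fold_models)
    if n_models == 0:
        raise ValueError("no fold models")
    gidx = np.array([graph.index(g) for g in genes])
    per_model = np.empty((n_models, len(genes)))
    eligible = np.zeros((n_models, len(genes)), dtype=bool)
    for i, fm in enumerate(fold_models):
        probs = fm.model.predict_proba(graph, x)
        per_model[i] = probs[gidx]
        test = set(fm.test_genes)
        for j, g in enumerate(genes):
            eligible[i, j] = (g in held_out) or (g in test)
    return PredictionTable(genes, per_model, eligible)


# ----------------------------------------------------------------------
# hyperparameter search


DEFAULT_SEARCH_SPACE = {
    "width": [8, 16, 32],
    "n_pre": [1, 2],
    "n_gnn": [1, 2],
    "n_post": [1, 2],
    "learning_rate": [1e-3, 3e-3, 1e-2, 3e-2],
    "dropout": [0.0, 0.1, 0.3],
    "k_neighbours": [50, 100, 200],
}


def tune(
    search_space: dict,
    graph: GeneGraph,
    x: np.ndarray,
    labels: LabelSet,
    cv: CVPlan,
    train_genes,
    budget: int = 50,
    seed: int = 0,
    base_config: GINConfig | None = None,
    evaluator=None,
    max_folds: int | None = None,
) -> tuple[GINConfig, float]:
    """Sequential search over the design space maximizing the mean CV
    test-fold ROC-AUC; returns the incumbent config and its objective.

    Candidates are sampled uniformly from ``search_space`` (a sequential
    optimizer satisfying the monotone-incumbent contract).  ``evaluator``
    may replace the objective (used in tests); ``max_folds`` caps the number
    of CV folds evaluated per trial.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if base_config is None:
        base_config = GINConfig(d_in=x.shape[1])
    rng = np.random.default_rng(seed)
    best_cfg, best_score = None, -np.inf
    failures = 0
    for _ in range(budget):
        params = {k: v[int(rng.integers(len(v)))] for k, v in search_space.items()}
        cfg = replace(base_config, **params)
        try:
            if evaluator is not None:
                score = float(evaluator(cfg))
            else:
                score = _cv_objective(cfg, graph, x, labels, cv, train_genes,
                                      seed=int(rng.integers(2**31)), max_folds=max_folds)
        except (FloatingPointError, ValueError):
            failures += 1
            continue
        if score > best_score:
            best_cfg, best_score = cfg, score
    if best_cfg is None:
        raise RuntimeError(f"all {failures} trials failed")
    return best_cfg, best_score


def _cv_objective(cfg, graph, x, labels, cv, train_genes, seed, max_folds=None):
    aucs = []
    root = np.random.default_rng(seed)
    items = sorted(cv.assignment.items())
    if max_folds is not None:
        items = items[:max_folds]
    for (r, f), test_genes in items:
        fold_train = cv.train_fold_genes(r, f, train_genes)
        balanced = undersample(fold_train, labels, seed=int(root.integers(2**31)))
        model = train_gin(cfg, graph, x, balanced, labels, seed=int(root.integers(2**31)))
        probs = model.predict_proba(graph, x, genes=test_genes)
        aucs.append(roc_auc(probs, labels.y(list(test_genes))))
    return float(np.mean(aucs))


def shortlist(predictions: PredictionTable, labels: LabelSet, top_n: int = 300) -> list[str]:
    """Top-ranked genes with positively labelled instances removed,
    order preserved."""
    ranked = predictions.ranked_genes()[:top_n]
    return [g for g in ranked if g not in labels.positives]
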