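"""Permutation-based interpretability for trained fold models.

Three procedures, all operating on frozen models (no retraining):

* node-feature permutation — shuffle a feature column (or a biological
  category of columns) across genes and measure the ROC-AUC drop;
* degree-preserving network permutation — rewire the whole interaction
  graph by local edge swaps that preserve every node's degree, and measure
  the training-set ROC-AUC under the corrupted topology;
* pathway permutation — shuffle only the edges internal to one pathway and
  measure the median absolute change in a single target gene's score,
  normalized by the square root of the pathway's edge count.

All procedures return copies; the input graph and features are never
modified in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import roc_auc
from .graphio import FeatureTable, GeneGraph, LabelSet, PathwaySet, induced_pathway_edges
from .training import FoldModelSet, SplitPlan

#: minimum induced edges for a pathway permutation to be meaningful
MIN_PERMUTABLE_EDGES = 2

#: proposals per fully randomized network draw, as a multiple of |E|
XSWAP_PROPOSALS_PER_EDGE = 10


@dataclass
class ImportanceRecord:
    scope: str  # feature | category | network | pathway
    identifier: str
    importance: float
    n_permutations: int
    dispersion: float = float("nan")
    eval_set: str = "cv-train"
    details: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# degree-preserving edge permutation


def _swap_edges(
    edges: list[tuple[str, str]],
    forbidden: set[tuple[str, str]],
    n_proposals: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Local edge swapping on ``edges``: propose (a,d),(c,b) from a random
    pair (a,b),(c,d) with random orientations; reject proposals creating a
    self-loop or an edge already present (in ``edges`` or ``forbidden``).
    The degree multiset over the touched node set is exactly preserved."""
    edges = [tuple(e) for e in edges]
    present = {tuple(sorted(e)) for e in edges}
    if len(edges) < 2:
        return edges
    for _ in range(n_proposals):
        i, j = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            a, b = b, a
        if rng.random() < 0.5:
            c, d = d, c
        e1, e2 = (a, d), (c, b)
        k1, k2 = tuple(sorted(e1)), tuple(sorted(e2))
        if a == d or c == b or k1 == k2:
            continue
        if k1 in present or k1 in forbidden or k2 in present or k2 in forbidden:
            continue
        present.discard(tuple(sorted(edges[i])))
        present.discard(tuple(sorted(edges[j])))
        present.add(k1)
        present.add(k2)
        edges[i], edges[j] = e1, e2
    return edges


def xswap(graph: GeneGraph, n_swaps: int | None = None, seed: int | None = None) -> GeneGraph:
    """Degree-preserving permutation of the whole graph.

    ``n_swaps`` is the proposal budget (default 10x the edge count, enough
    to fully randomize); rejected proposals (self-loop or duplicate) leave
    the graph unchanged.  Returns a new graph; the input is untouched.
    """
    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges)
    if n_swaps is None:
        n_swaps = XSWAP_PROPOSALS_PER_EDGE * len(edges)
    new_edges = _swap_edges(edges, forbidden=set(), n_proposals=n_swaps, rng=rng)
    permuted = graph.replace_edges(new_edges)
    assert sorted(permuted.degree_sequence()) == sorted(graph.degree_sequence())
    assert permuted.n_edges == graph.n_edges
    return permuted


def permute_pathway_edges(
    graph: GeneGraph,
    pathway_genes,
    n_swaps: int | None = None,
    seed: int | None = None,
) -> GeneGraph:
    """Shuffle only the edges whose both endpoints lie in ``pathway_genes``,
    keeping every other edge fixed (degree-preserving within the pathway)."""
    rng = np.random.default_rng(seed)
    internal = sorted(induced_pathway_edges(graph, pathway_genes))
    fixed = graph.edges - set(internal)
    if n_swaps is None:
        n_swaps = max(1, XSWAP_PROPOSALS_PER_EDGE * len(internal))
    new_internal = _swap_edges(internal, forbidden={tuple(sorted(e)) for e in fixed},
                               n_proposals=n_swaps, rng=rng)
    permuted = graph.replace_edges(sorted(fixed) + list(new_internal))
    assert sorted(permuted.degree_sequence()) == sorted(graph.degree_sequence())
    return permuted


# ----------------------------------------------------------------------
# feature permutation


def _eval_genes(fm, eval_set: str, split: SplitPlan | None):
    if eval_set == "cv-train":
        return list(fm.train_genes)
    if eval_set == "cv-test":
        return list(fm.test_genes)
    if eval_set == "held-out":
        if split is None:
            raise ValueError("held-out evaluation needs the outer split plan")
        return list(split.held_out)
    raise ValueError(f"unknown eval set {eval_set!r}")


def feature_importance(
    models: FoldModelSet,
    graph: GeneGraph,
    features: FeatureTable,
    labels: LabelSet,
    target: str,
    n_perm: int = 500,
    eval_set: str = "cv-train",
    seed: int | None = None,
    split: SplitPlan | None = None,
    category_mode: str = "independent",
) -> ImportanceRecord:
    """Permutation importance of one feature or one biological category.

    Per permutation the column is shuffled across all genes and every fold
    model's ROC-AUC on its evaluation genes is recomputed with frozen
    parameters.  On the CV training set the importance is the signed drop
    (original - mean permuted); on CV-test / held-out sets the absolute
    difference is reported.  A category aggregates its member features'
    importances (each member shuffled independently, ``category_mode=
    "independent"``) or shuffles all member columns jointly per draw
    (``"joint"``).
    """
    cats = features.categories
    if target in features.feature_names:
        columns = [target]
        scope = "feature"
    elif target in cats:
        columns = cats[target]
        scope = "category"
    else:
        raise ValueError(f"unknown feature or category {target!r}")

    if scope == "category" and category_mode == "independent":
        records = [
            feature_importance(models, graph, features, labels, col, n_perm=n_perm,
                               eval_set=eval_set, seed=None if seed is None else seed + k,
                               split=split)
            for k, col in enumerate(columns)
        ]
        diffs = np.concatenate([r.details["diffs"] for r in records])
        return ImportanceRecord(
            scope="category",
            identifier=target,
            importance=float(np.mean([r.importance for r in records])),
            n_permutations=len(columns) * n_perm,
            dispersion=float(np.std(diffs, ddof=1)) if len(diffs) > 1 else float("nan"),
            eval_set=eval_set,
            details={"members": {r.identifier: r.importance for r in records},
                     "diffs": diffs},
        )

    rng = np.random.default_rng(seed)
    x = features.matrix()
    col_idx = [list(features.feature_names).index(c) for c in columns]
    n_genes = x.shape[0]

    originals = []
    eval_sets = []
    for fm in models:
        genes = _eval_genes(fm, eval_set, split)
        gidx = np.array([graph.index(g) for g in genes])
        y = labels.y(genes)
        probs = fm.model.predict_proba(graph, x)
        originals.append(roc_auc(probs[gidx], y))
        eval_sets.append((gidx, y))

    diffs = []  # original - permuted, one per (model, permutation)
    for _ in range(n_perm):
        xp = x.copy()
        for c in col_idx:
            xp[:, c] = xp[rng.permutation(n_genes), c]
        for (gidx, y), orig, fm in zip(eval_sets, originals, models):
            probs = fm.model.predict_proba(graph, xp)
            diffs.append(orig - roc_auc(probs[gidx], y))
    diffs = np.asarray(diffs)
    mean_drop = float(diffs.mean())
    importance = mean_drop if eval_set == "cv-train" else abs(mean_drop)
    return ImportanceRecord(
        scope=scope,
        identifier=target,
        importance=importance,
        n_permutations=n_perm,
        dispersion=float(np.std(diffs, ddof=1)) if len(diffs) > 1 else float("nan"),
        eval_set=eval_set,
        details={"diffs": diffs, "original_auc": float(np.mean(originals))},
    )


def _threshold_for_specificity(scores: np.ndarray, y: np.ndarray, specificity: float) -> float:
    """Smallest observed score threshold (predict positive at score >=
    threshold) whose specificity reaches the target."""
    neg = scores[y == 0]
    if len(neg) == 0:
        raise ValueError("no negatives to compute specificity")
    for th in np.sort(np.unique(scores)):
        spec = float(np.mean(neg < th))
        if spec >= specificity:
            return float(th)
    raise ValueError(f"specificity {specificity} unreachable on these scores")


def recall_importance(
    models: FoldModelSet,
    graph: GeneGraph,
    features: FeatureTable,
    labels: LabelSet,
    target: str,
    specificity: float = 0.9,
    n_perm: int = 500,
    eval_set: str = "cv-train",
    seed: int | None = None,
    split: SplitPlan | None = None,
) -> ImportanceRecord:
    """Sensitivity variant: fix the decision threshold at a specificity
    level on the original scores, then report the absolute change in recall
    after permuting the feature."""
    if target not in features.feature_names:
        raise ValueError(f"unknown feature {target!r}")
    rng = np.random.default_rng(seed)
    x = features.matrix()
    c = list(features.feature_names).index(target)
    n_genes = x.shape[0]

    per_model = []
    for fm in models:
        genes = _eval_genes(fm, eval_set, split)
        gidx = np.array([graph.index(g) for g in genes])
        y = labels.y(genes)
        scores = fm.model.predict_proba(graph, x)[gidx]
        th = _threshold_for_specificity(scores, y, specificity)
        pos = y == 1
        recall_orig = float(np.mean(scores[pos] >= th))
        per_model.append((gidx, y, th, recall_orig))

    diffs = []
    for _ in range(n_perm):
        xp = x.copy()
        xp[:, c] = xp[rng.permutation(n_genes), c]
        for fm, (gidx, y, th, recall_orig) in zip(models, per_model):
            scores = fm.model.predict_proba(graph, xp)[gidx]
            recall_perm = float(np.mean(scores[y == 1] >= th))
            diffs.append(recall_orig - recall_perm)
    diffs = np.asarray(diffs)
    return ImportanceRecord(
        scope="feature",
        identifier=target,
        importance=float(abs(diffs.mean())),
        n_permutations=n_perm,
        dispersion=float(np.std(diffs, ddof=1)) if len(diffs) > 1 else float("nan"),
        eval_set=eval_set,
        details={"specificity": specificity,
                 "recall_original": float(np.mean([r for *_, r in per_model]))},
    )


# ----------------------------------------------------------------------
# network permutation


def network_importance(
    models: FoldModelSet,
    graph: GeneGraph,
    features: FeatureTable,
    labels: LabelSet,
    n_perm: int = 500,
    seed: int | None = None,
    n_swaps: int | None = None,
) -> dict:
    """Training-set ROC-AUC of every fold model on degree-preserving
    permuted graphs.

    Each fold model is evaluated on ``n_perm`` independently rewired
    networks (frozen parameters), yielding ``len(models) * n_perm``
    permuted evaluations.  Returns the original per-model AUCs, the full
    permuted AUC matrix and the mean drop.
    """
    rng = np.random.default_rng(seed)
    x = features.matrix()
    originals = np.empty(len(models))
    permuted = np.empty((len(models), n_perm))
    for i, fm in enumerate(models):
        gidx = np.array([graph.index(g) for g in fm.train_genes])
        y = labels.y(list(fm.train_genes))
        originals[i] = roc_auc(fm.model.predict_proba(graph, x)[gidx], y)
        for p in range(n_perm):
            g_perm = xswap(graph, n_swaps=n_swaps, seed=int(rng.integers(2**31)))
            permuted[i, p] = roc_auc(fm.model.predict_proba(g_perm, x)[gidx], y)
    return {
        "original": originals,
        "permuted": permuted,
        "importance": float(originals.mean() - permuted.mean()),
    }


# ----------------------------------------------------------------------
# pathway permutation


def pathway_importance(
    model,
    graph: GeneGraph,
    features: FeatureTable,
    pathways: PathwaySet,
    target: str,
    n_perm: int = 100,
    seed: int | None = None,
    min_edges: int = MIN_PERMUTABLE_EDGES,
) -> list[ImportanceRecord]:
    """Pathway-restricted permutation importance for one target gene.

    For every pathway containing the target with at least ``min_edges``
    internal edges, the internal edges are rewired ``n_perm`` times; the
    raw importance is the median absolute change of the target's score and
    the reported importance divides by sqrt(edge count).  Pathways not
    containing the target or with too few internal edges are returned
    flagged ``permuted=False``.
    """
    if target not in graph:
        raise ValueError(f"target gene {target!r} not in graph")
    memberships = pathways.containing(target)
    if not memberships:
        raise ValueError(f"target gene {target!r} belongs to no pathway")
    rng = np.random.default_rng(seed)
    x = features.matrix()
    score_orig = float(model.predict_proba(graph, x, genes=[target])[0])
    records = []
    for pid, genes in pathways.items():
        contains = target in genes
        edges = induced_pathway_edges(graph, genes)
        if not contains or len(edges) < min_edges:
            reason = "target not member" if not contains else "insufficient edges to permute"
            records.append(ImportanceRecord(
                scope="pathway", identifier=pid, importance=float("nan"),
                n_permutations=0, eval_set="eval",
                details={"permuted": False, "reason": reason, "n_edges": len(edges)},
            ))
            continue
        deltas = np.empty(n_perm)
        for p in range(n_perm):
            g_perm = permute_pathway_edges(graph, genes, seed=int(rng.integers(2**31)))
            deltas[p] = abs(float(model.predict_proba(g_perm, x, genes=[target])[0]) - score_orig)
        raw = float(np.median(deltas))
        records.append(ImportanceRecord(
            scope="pathway", identifier=pid,
            importance=raw / np.sqrt(len(edges)),
            n_permutations=n_perm,
            dispersion=float(np.std(deltas, ddof=1)) if n_perm > 1 else float("nan"),
            eval_set="eval",
            details={"permuted": True, "raw": raw, "n_edges": len(edges)},
        ))
    return records
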