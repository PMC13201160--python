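"""Loading, validation and alignment of the gene graph, node features and labels.

The message-passing substrate is a simple undirected gene--gene interaction
network.  Node features arrive as a genes x features matrix with explicit
missing markers plus a sidecar describing, for every feature, its biological
category and how missing entries are to be treated.  Positive target labels,
clinical-phase annotations and the time-sliced target list are plain gene
lists.  Everything is aligned to the graph before modelling: genes absent
from the network carry no message-passing context and are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

#: Recognised missingness classes, in the vocabulary used throughout.
MISSINGNESS_CLASSES = frozenset(
    {"pseudo", "true-median-train", "true-median-split", "true-exclude", "true-zero"}
)

#: Clinical phase vocabulary (``NA`` = no phase information).
PHASES = ("approved", "phase III", "phase II", "phase I", "NA")


class GeneGraph:
    """Simple undirected gene-interaction graph.

    Nodes are case-sensitive gene symbols.  Self-loops and duplicate edges
    are rejected at construction; loaders drop them silently with a logged
    count.  ``neighbours(g)`` returns the adjacency set N(g) consumed by the
    GIN aggregation.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        self.nodes: tuple[str, ...] = tuple(dict.fromkeys(nodes))
        self._index = {g: i for i, g in enumerate(self.nodes)}
        self._adj: dict[str, set[str]] = {g: set() for g in self.nodes}
        self._edges: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop {a!r}-{b!r} not allowed")
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge endpoint not a registered node: {(a, b)!r}")
            key = (a, b) if a < b else (b, a)
            if key in self._edges:
                raise ValueError(f"duplicate edge {key!r}")
            self._edges.add(key)
            self._adj[a].add(b)
            self._adj[b].add(a)

    # -- basic queries -------------------------------------------------
    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index(self, gene: str) -> int:
        return self._index[gene]

    def neighbours(self, gene: str) -> set[str]:
        return set(self._adj[gene])

    def degree(self, gene: str) -> int:
        return len(self._adj[gene])

    def degree_sequence(self) -> tuple[int, ...]:
        return tuple(len(self._adj[g]) for g in self.nodes)

    def copy(self) -> "GeneGraph":
        return GeneGraph(self.nodes, self._edges)

    def replace_edges(self, edges: Iterable[tuple[str, str]]) -> "GeneGraph":
        """New graph over the same node set with a different edge set."""
        return GeneGraph(self.nodes, edges)

    def induced_subgraph(self, genes: Iterable[str]) -> "GeneGraph":
        keep = set(genes)
        nodes = [g for g in self.nodes if g in keep]
        edges = [(a, b) for a, b in self._edges if a in keep and b in keep]
        return GeneGraph(nodes, edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self._edges)
        return g

    def adjacency(self):
        """Sparse CSR adjacency in node order (symmetric, 0/1)."""
        from scipy.sparse import csr_matrix

        rows, cols = [], []
        for a, b in self._edges:
            ia, ib = self._index[a], self._index[b]
            rows += [ia, ib]
            cols += [ib, ia]
        data = np.ones(len(rows))
        return csr_matrix((data, (rows, cols)), shape=(self.n_nodes, self.n_nodes))

    def subgraph_nodes(self, genes: Iterable[str]) -> set[str]:
        return {g for g in genes if g in self._index}


@dataclass(frozen=True)
class LoadReport:
    n_nodes: int
    n_edges: int
    n_duplicates: int
    n_self_loops: int


@dataclass(frozen=True)
class FeatureSpec:
    """Per-feature metadata: biological category and missingness policy."""

    name: str
    category: str
    missingness_class: str = "pseudo"

    def __post_init__(self):
        if self.missingness_class not in MISSINGNESS_CLASSES:
            raise ValueError(
                f"unknown missingness class {self.missingness_class!r} for "
                f"feature {self.name!r}; expected one of {sorted(MISSINGNESS_CLASSES)}"
            )


class FeatureTable:
    """Genes x features matrix with per-feature :class:`FeatureSpec` metadata.

    Missing entries are ``NaN`` until :func:`impute` is applied.
    """

    def __init__(self, values: pd.DataFrame, specs: Sequence[FeatureSpec]):
        specs = list(specs)
        if len(specs) != values.shape[1]:
            raise ValueError(
                f"{values.shape[1]} feature columns but {len(specs)} specs"
            )
        by_name = {s.name: s for s in specs}
        if set(by_name) != set(values.columns):
            raise ValueError("spec names do not match feature columns")
        # keep spec order aligned with column order
        self.values = values.copy()
        self.specs = [by_name[c] for c in values.columns]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def spec(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def categories(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.specs:
            out.setdefault(s.category, []).append(s.name)
        return out

    def missingness_indicators(self) -> pd.DataFrame:
        """Binary gene x feature indicators of missing entries (pre-imputation).

        Used as stratification keys for the outer train/held-out split.
        """
        return self.values.isna().astype(int)

    def matrix(self, genes: Sequence[str] | None = None) -> np.ndarray:
        df = self.values if genes is None else self.values.loc[list(genes)]
        return df.to_numpy(dtype=float)

    def reindex(self, genes: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(genes)], self.specs)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.specs)


@dataclass
class LabelSet:
    """Positive targets, clinical phases and the time-sliced target set.

    Under the closed-world assumption, any gene not in ``positives`` is a
    negative during training.  ``timesliced`` genes entered trials after the
    label freeze; they must be disjoint from the positives.
    """

    positives: set[str]
    phases: dict[str, str] = field(default_factory=dict)
    timesliced: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = self.positives & self.timesliced
        if overlap:
            raise ValueError(
                f"time-sliced genes overlap positives: {sorted(overlap)[:5]}"
            )
        bad = set(self.phases.values()) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase annotations: {sorted(bad)}")

    def y(self, genes: Sequence[str]) -> np.ndarray:
        """0/1 label vector over ``genes`` (closed world)."""
        return np.array([1 if g in self.positives else 0 for g in genes], dtype=int)

    def restrict(self, genes: Iterable[str]) -> "LabelSet":
        keep = set(genes)
        return LabelSet(
            positives=self.positives & keep,
            phases={g: p for g, p in self.phases.items() if g in keep},
            timesliced=self.timesliced & keep,
        )


class PathwaySet:
    """Pathway id -> gene set mapping (GMT-style)."""

    def __init__(self, pathways: Mapping[str, Iterable[str]]):
        self.pathways: dict[str, set[str]] = {
            k: set(v) for k, v in pathways.items()
        }

    def __getitem__(self, key: str) -> set[str]:
        return self.pathways[key]

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self):
        return len(self.pathways)

    def items(self):
        return self.pathways.items()

    def containing(self, gene: str) -> list[str]:
        return [p for p, genes in self.pathways.items() if gene in genes]


# ----------------------------------------------------------------------
# loaders


def load_edge_list(source, header: bool = False) -> tuple[GeneGraph, LoadReport]:
    """Read a two-column TSV of gene pairs into a :class:`GeneGraph`.

    Duplicate edges (in either orientation) and self-loops are dropped
    silently with a logged count.  Raises on malformed rows (naming the line
    number) and on an empty edge list.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]
    if header and lines:
        lines = lines[1:]

    nodes: dict[str, None] = {}
    edges: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    n_rows = 0
    for lineno, line in enumerate(lines, start=2 if header else 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"malformed edge row at line {lineno}: {line!r}")
        a, b = parts[0].strip(), parts[1].strip()
        n_rows += 1
        nodes.setdefault(a)
        nodes.setdefault(b)
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in edges:
            n_dup += 1
            continue
        edges.add(key)
    if n_rows == 0:
        raise ValueError("empty edge list")
    graph = GeneGraph(nodes, edges)
    if n_self or n_dup:
        logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
    return graph, LoadReport(graph.n_nodes, graph.n_edges, n_dup, n_self)


def load_feature_table(matrix_tsv, specs_json) -> FeatureTable:
    """Feature matrix TSV (header = feature names, first column = gene) plus
    a JSON sidecar mapping feature name -> {category, missingness_class}.

    Empty cells and ``NA`` are both accepted as missing markers.
    """
    df = pd.read_csv(matrix_tsv, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    if isinstance(specs_json, (str, Path)):
        meta = json.loads(Path(specs_json).read_text())
    else:
        meta = specs_json
    specs = [
        FeatureSpec(
            name=c,
            category=meta[c]["category"],
            missingness_class=meta[c].get("missingness_class", "pseudo"),
        )
        for c in df.columns
    ]
    return FeatureTable(df, specs)


def load_labels(labels_tsv, timesliced=None) -> LabelSet:
    """Labels TSV with columns (gene, phase); optional time-sliced gene list
    (one symbol per line)."""
    df = pd.read_csv(labels_tsv, sep="\t", header=None, names=["gene", "phase"],
                     dtype=str, na_values=[], keep_default_na=False)
    phases = {r.gene: (r.phase if r.phase else "NA") for r in df.itertuples()}
    ts: set[str] = set()
    if timesliced is not None:
        if isinstance(timesliced, (str, Path)):
            ts = {ln.strip() for ln in Path(timesliced).read_text().splitlines() if ln.strip()}
        else:
            ts = set(timesliced)
    return LabelSet(positives=set(phases), phases=phases, timesliced=ts)


def load_gmt(source) -> PathwaySet:
    """GMT: pathway-id <tab> description <tab> gene1 <tab> gene2 ..."""
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    pathways = {}
    for line in lines:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        pathways[parts[0]] = set(p for p in parts[2:] if p)
    return PathwaySet(pathways)


# ----------------------------------------------------------------------
# alignment and imputation


def align_to_graph(
    features: FeatureTable, labels: LabelSet, graph: GeneGraph
) -> tuple[FeatureTable, LabelSet, dict]:
    """Drop genes absent from the graph; report retained fractions.

    Raises if the feature table shares no gene with the graph.
    """
    in_graph = [g for g in features.genes if g in graph]
    if not in_graph:
        raise ValueError("no overlap between feature-table genes and graph nodes")
    dropped = [g for g in features.genes if g not in graph]
    report = {
        "n_input": len(features.genes),
        "n_retained": len(in_graph),
        "retained_fraction": len(in_graph) / len(features.genes),
        "dropped": dropped,
    }
    return features.reindex(in_graph), labels.restrict(in_graph), report


def retained_fractions(split, graph: GeneGraph) -> dict[str, float]:
    """Per-partition fraction of split genes present in the graph."""
    out = {}
    for name, genes in (("train", split.train), ("held_out", split.held_out)):
        genes = list(genes)
        out[name] = sum(g in graph for g in genes) / len(genes) if genes else float("nan")
    return out


def impute(
    features: FeatureTable,
    train_genes: Iterable[str],
    held_out_genes: Iterable[str] = (),
) -> FeatureTable:
    """Apply the per-class imputation policy; deterministic given the input.

    * ``pseudo`` and ``true-zero``: missing -> 0.  A pseudo-missing value is
      a genuine zero (no association reported); true-zero covers topological
      specificity scores where absence is scored as no influence.
    * ``true-median-train``: missing -> median computed on the training
      partition, used for both partitions.
    * ``true-median-split``: missing in the training partition -> training
      median; missing in the held-out partition -> held-out median.
    * ``true-exclude``: genes missing the feature are dropped entirely.

    Returns a new table (possibly with fewer genes under ``true-exclude``).
    """
    train_genes = [g for g in train_genes if g in features.values.index]
    held_out_genes = [g for g in held_out_genes if g in features.values.index]
    df = features.values.copy()

    # drop genes missing any true-exclude feature first
    excl_cols = [s.name for s in features.specs if s.missingness_class == "true-exclude"]
    if excl_cols:
        keep_mask = ~df[excl_cols].isna().any(axis=1)
        df = df.loc[keep_mask]
        train_genes = [g for g in train_genes if g in df.index]
        held_out_genes = [g for g in held_out_genes if g in df.index]

    for s in features.specs:
        col = df[s.name]
        if s.missingness_class in ("pseudo", "true-zero"):
            df[s.name] = col.fillna(0.0)
        elif s.missingness_class == "true-median-train":
            med = col.loc[train_genes].median(skipna=True)
            if np.isnan(med):
                raise ValueError(
                    f"feature {s.name!r}: all training values missing under a "
                    "median policy"
                )
            df[s.name] = col.fillna(med)
        elif s.missingness_class == "true-median-split":
            med_tr = col.loc[train_genes].median(skipna=True)
            if np.isnan(med_tr):
                raise ValueError(
                    f"feature {s.name!r}: all training values missing under a "
                    "median policy"
                )
            filled = col.copy()
            tr_missing = [g for g in train_genes if np.isnan(col.loc[g])]
            filled.loc[tr_missing] = med_tr
            if held_out_genes:
                med_ho = col.loc[held_out_genes].median(skipna=True)
                if np.isnan(med_ho):
                    raise ValueError(
                        f"feature {s.name!r}: all held-out values missing under "
                        "a median policy"
                    )
                ho_missing = [g for g in held_out_genes if np.isnan(col.loc[g])]
                filled.loc[ho_missing] = med_ho
            df[s.name] = filled
        # true-exclude handled above
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values remain after imputation in {bad}")
    return FeatureTable(df, features.specs)


def induced_pathway_edges(graph: GeneGraph, pathway: Iterable[str]) -> set[tuple[str, str]]:
    """Edges of ``graph`` with BOTH endpoints in ``pathway``."""
    members = set(pathway)
    return {(a, b) for a, b in graph.edges if a in members and b in members}
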