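"""GIN node classifier: pre-processing stack, linear-GIN message passing with
neighbour sampling, post-processing stack and a sigmoid probability head.

The message-passing update is

    x_i <- DROPOUT(ReLU(BN(LINEAR((1 + eps) * x_i + sum_{j in N_s(i)} x_j))))

with sum aggregation over a (possibly sampled) neighbourhood N_s(i), and the
pre-/post-processing stacks apply the same DROPOUT(ReLU(BN(LINEAR(.))))
block without message passing.  Widths expand by a factor of 2 from the
pre-processing stack to the GIN layers and contract by the same factor into
the post-processing stack; the head is a single linear unit + sigmoid.

The model is inductive: a forward pass scores any node given its features
and edges, whether or not it was seen in training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
from scipy import sparse

from ._nn import Linear, BatchNorm, ReLU, Dropout, sigmoid
from .graphio import GeneGraph


@dataclass
class GINConfig:
    """Architecture and training hyperparameters.

    ``width`` is the base embedding size w: the pre-processing stack ends at
    w, GIN layers run at 2w, and the post-processing stack contracts back to
    w before the scalar head.  ``k_neighbours`` caps the number of
    neighbours sampled per node per message-passing layer ("all" disables
    sampling); the searched values are 50, 100 and 200.
    """

    d_in: int
    width: int = 16
    n_pre: int = 1
    n_gnn: int = 2
    n_post: int = 1
    epsilon: float = 0.0
    dropout: float = 0.1
    k_neighbours: int | str = "all"
    learning_rate: float = 1e-2
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if min(self.n_pre, self.n_gnn, self.n_post) < 1:
            raise ValueError("layer counts must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.k_neighbours != "all" and int(self.k_neighbours) < 1:
            raise ValueError('k_neighbours must be >= 1 or "all"')


def width_schedule(config: GINConfig) -> list[tuple[str, int, int]]:
    """Per-layer (name, d_in, d_out) widths implied by the factor-2 rule."""
    if config.width < 1:
        raise ValueError("width must be >= 1")
    w = config.width
    dims: list[tuple[str, int, int]] = []
    d = config.d_in
    for i in range(config.n_pre):
        dims.append((f"pre{i}", d, w))
        d = w
    for i in range(config.n_gnn):
        dims.append((f"gin{i}", d, 2 * w))
        d = 2 * w
    for i in range(config.n_post):
        dims.append((f"post{i}", d, w))
        d = w
    dims.append(("head", w, 1))
    return dims


def sample_neighbours(
    graph: GeneGraph, node: str, k: int | str, rng: np.random.Generator
) -> set[str]:
    """Uniform sample without replacement of min(k, degree) neighbours."""
    nbrs = sorted(graph.neighbours(node))
    if k == "all" or len(nbrs) <= int(k):
        return set(nbrs)
    picked = rng.choice(len(nbrs), size=int(k), replace=False)
    return {nbrs[i] for i in picked}


def sampled_adjacency(
    graph: GeneGraph, k: int | str, rng: np.random.Generator | None = None
) -> sparse.csr_matrix:
    """Row-stochastic-shaped 0/1 matrix S with S[i, j] = 1 iff j is among the
    (sampled) neighbours of i.  With ``k="all"`` this is the symmetric
    adjacency; under sampling rows are drawn independently, so S need not be
    symmetric."""
    n = graph.n_nodes
    if k == "all":
        return graph.adjacency().tocsr()
    if rng is None:
        raise ValueError("neighbour sampling requires an rng")
    k = int(k)
    rows, cols = [], []
    for i, g in enumerate(graph.nodes):
        nbrs = sorted(graph.neighbours(g))
        if len(nbrs) > k:
            idx = rng.choice(len(nbrs), size=k, replace=False)
            nbrs = [nbrs[j] for j in idx]
        for nb in nbrs:
            rows.append(i)
            cols.append(graph.index(nb))
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


class _Block:
    """DROPOUT(ReLU(BN(LINEAR(x)))) with cached backward."""

    def __init__(self, d_in: int, d_out: int, dropout: float, rng: np.random.Generator):
        self.linear = Linear(d_in, d_out, rng)
        self.bn = BatchNorm(d_out)
        self.relu = ReLU()
        self.dropout = Dropout(dropout)

    def forward(self, x, training, rng=None):
        h = self.linear.forward(x, training)
        h = self.bn.forward(h, training)
        h = self.relu.forward(h, training)
        return self.dropout.forward(h, training, rng)

    def backward(self, dy):
        dy = self.dropout.backward(dy)
        dy = self.relu.backward(dy)
        dy = self.bn.backward(dy)
        return self.linear.backward(dy)

    def parameters(self):
        return self.linear.parameters() + self.bn.parameters()


class GINModel:
    """The trained network; layers laid out per :func:`width_schedule`.

    In eval mode (``training=False``) forward passes are pure functions:
    dropout is off and batch-normalization uses frozen running statistics.
    """

    def __init__(self, config: GINConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.pre: list[_Block] = []
        self.gin: list[_Block] = []
        self.post: list[_Block] = []
        for name, d_in, d_out in width_schedule(config):
            if name.startswith("pre"):
                self.pre.append(_Block(d_in, d_out, config.dropout, rng))
            elif name.startswith("gin"):
                self.gin.append(_Block(d_in, d_out, config.dropout, rng))
            elif name.startswith("post"):
                self.post.append(_Block(d_in, d_out, config.dropout, rng))
        self.head = Linear(config.width, 1, rng)
        self._agg_cache: list[sparse.spmatrix] = []

    # -- forward / backward -------------------------------------------
    def layers(self):
        return self.pre + self.gin + self.post + [self.head]

    def forward_logits(
        self,
        x: np.ndarray,
        adjacencies: Sequence[sparse.spmatrix],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Full-batch forward over all rows of ``x``; one (sampled)
        adjacency per GIN layer."""
        if len(adjacencies) != len(self.gin):
            raise ValueError(
                f"{len(self.gin)} GIN layers need {len(self.gin)} adjacencies, "
                f"got {len(adjacencies)}"
            )
        eps = self.config.epsilon
        h = x
        for blk in self.pre:
            h = blk.forward(h, training, rng)
        self._agg_cache = list(adjacencies)
        for blk, S in zip(self.gin, adjacencies):
            agg = (1.0 + eps) * h + S @ h
            h = blk.forward(agg, training, rng)
        for blk in self.post:
            h = blk.forward(h, training, rng)
        return self.head.forward(h, training)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        eps = self.config.epsilon
        dy = self.head.backward(dlogits[:, None])
        for blk in reversed(self.post):
            dy = blk.backward(dy)
        for blk, S in zip(reversed(self.gin), reversed(self._agg_cache)):
            d_agg = blk.backward(dy)
            dy = (1.0 + eps) * d_agg + S.T @ d_agg
        for blk in reversed(self.pre):
            dy = blk.backward(dy)

    # -- public prediction surface ------------------------------------
    def predict_proba(
        self,
        graph: GeneGraph,
        x: np.ndarray,
        genes: Sequence[str] | None = None,
        k: int | str | None = None,
        seed: int | None = None,
        adjacencies: Sequence[sparse.spmatrix] | None = None,
    ) -> np.ndarray:
        """Eval-mode probabilities, optionally restricted to ``genes``.

        By default the full neighbourhood is used (deterministic); pass
        ``k``/``seed`` to reproduce sampled message passing, or supply
        precomputed ``adjacencies`` directly.
        """
        if adjacencies is None:
            kk = "all" if k is None else k
            rng = np.random.default_rng(seed) if seed is not None else None
            if kk != "all" and rng is None:
                raise ValueError("sampled prediction requires a seed")
            adjacencies = [
                sampled_adjacency(graph, kk, rng) for _ in range(len(self.gin))
            ]
        probs = sigmoid(self.forward_logits(x, adjacencies, training=False))
        if genes is None:
            return probs
        idx = [graph.index(g) for g in genes]
        return probs[idx]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def block_state(blk: _Block) -> dict:
            return {
                "W": blk.linear.W.tolist(),
                "b": blk.linear.b.tolist(),
                "gamma": blk.bn.gamma.tolist(),
                "beta": blk.bn.beta.tolist(),
                "running_mean": blk.bn.running_mean.tolist(),
                "running_var": blk.bn.running_var.tolist(),
            }

        return {
            "config": asdict(self.config),
            "pre": [block_state(b) for b in self.pre],
            "gin": [block_state(b) for b in self.gin],
            "post": [block_state(b) for b in self.post],
            "head": {"W": self.head.W.tolist(), "b": self.head.b.tolist()},
        }

    @classmethod
    def from_dict(cls, state: dict) -> "GINModel":
        model = cls(GINConfig(**state["config"]))
        for blocks, states in (
            (model.pre, state["pre"]),
            (model.gin, state["gin"]),
            (model.post, state["post"]),
        ):
            for blk, st in zip(blocks, states):
                blk.linear.W = np.asarray(st["W"])
                blk.linear.b = np.asarray(st["b"])
                blk.bn.gamma = np.asarray(st["gamma"])
                blk.bn.beta = np.asarray(st["beta"])
                blk.bn.running_mean = np.asarray(st["running_mean"])
                blk.bn.running_var = np.asarray(st["running_var"])
        model.head.W = np.asarray(state["head"]["W"])
        model.head.b = np.asarray(state["head"]["b"])
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GINModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def gin_layer_reference(
    x: np.ndarray, adjacency: np.ndarray, epsilon: float = 0.0
) -> np.ndarray:
    """Dense oracle for the GIN aggregation + ReLU with identity linear/BN:
    ReLU((A + (1 + eps) I) X).  Used only for cross-checks."""
    n = x.shape[0]
    return np.maximum((adjacency + (1.0 + epsilon) * np.eye(n)) @ x, 0.0)
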