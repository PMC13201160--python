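"""Self-contained synthetic fixtures with planted, tunable signal.

The generator emulates the shape of the real corpus — an interaction graph
with a heavy-tailed degree distribution, a genes x features matrix with
category and missingness metadata, positive / phase / time-sliced labels,
pathway gene sets, a differential-expression table and raw patient-level
cohort inputs — while planting a known latent target propensity so that
recovery can be scored against ground truth.

Planted signal has three routes, each individually tunable:

* designated signal features carry ``effect_size`` (in SD units) times the
  standardized propensity;
* homophilous attachment adds extra edges among high-propensity genes;
* the DEG Wald statistic is ``deg_alpha * propensity + noise``.

With every knob at zero the fixture is pure noise and a trained model
should sit at chance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .features import CohortOmics
from .graphio import FeatureSpec, FeatureTable, GeneGraph, LabelSet, PathwaySet


@dataclass
class SynthConfig:
    """Study conditions for a synthetic fixture.

    Defaults are the desk-scale benchmark conditions used throughout the
    test-suite: 2,000 genes, 100 positives, an effect of 1.5 SD on 3 of 20
    features and homophily 0.3.
    """

    n_genes: int = 2000
    attachment: int = 4  # preferential-attachment edges per new node (mean degree ~ 2x)
    n_pathways: int = 10
    pathway_size: int = 60
    n_positives: int = 100
    n_features: int = 20
    n_signal: int = 3
    effect_size: float = 1.5
    homophily: float = 0.3
    missing_rate: float = 0.05
    n_true_median_train: int = 2
    n_true_median_split: int = 2
    n_true_zero: int = 2
    n_true_exclude: int = 0
    deg_alpha: float = 2.0
    deg_noise_sd: float = 1.0
    n_timesliced: int = 30
    n_patients: int = 40
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "attachment", "n_pathways", "pathway_size",
                     "n_positives", "n_features", "n_timesliced", "n_patients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("homophily", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_signal > self.n_features:
            raise ValueError("more signal features than features")


@dataclass
class SynthBundle:
    graph: GeneGraph
    features: FeatureTable
    labels: LabelSet
    pathways: PathwaySet
    degs: pd.DataFrame
    omics: CohortOmics
    truth: dict = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate(config: SynthConfig) -> SynthBundle:
    """Generate a full fixture; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    # latent target propensity, standardized
    z = rng.standard_normal(config.n_genes)
    z = (z - z.mean()) / z.std()

    # positives drawn from the high-propensity pool (top 15%), time-sliced
    # targets from the remaining high-propensity unlabelled genes
    order = np.argsort(z)[::-1]
    pool_size = max(config.n_positives + config.n_timesliced,
                    int(0.15 * config.n_genes))
    pool = order[:pool_size]
    picked = rng.choice(len(pool), size=config.n_positives + config.n_timesliced,
                        replace=False)
    pos_idx = pool[picked[: config.n_positives]]
    ts_idx = pool[picked[config.n_positives:]]
    positives = {genes[i] for i in pos_idx}
    timesliced = {genes[i] for i in ts_idx}

    phase_choices = ["approved", "phase III", "phase II", "phase I"]
    phases = {genes[i]: phase_choices[int(rng.integers(4))] for i in pos_idx}
    labels = LabelSet(positives=positives, phases=phases, timesliced=timesliced)

    # graph: preferential attachment, then homophilous rewiring among the
    # high-propensity set
    g = nx.barabasi_albert_graph(config.n_genes, config.attachment,
                                 seed=int(rng.integers(2**31)))
    edges = {tuple(sorted((genes[a], genes[b]))) for a, b in g.edges}
    high = np.concatenate([pos_idx, ts_idx])
    n_extra = int(config.homophily * len(high) * config.attachment)
    added = 0
    while added < n_extra:
        a, b = rng.choice(high, size=2, replace=False)
        key = tuple(sorted((genes[a], genes[b])))
        if key in edges:
            continue
        edges.add(key)
        added += 1
    graph = GeneGraph(genes, sorted(edges))

    # features: signal columns carry effect * propensity, the rest pure noise
    signal_cols = [f"f{j:02d}" for j in range(config.n_signal)]
    values = rng.standard_normal((config.n_genes, config.n_features))
    for j in range(config.n_signal):
        values[:, j] += config.effect_size * z
    names = [f"f{j:02d}" for j in range(config.n_features)]
    categories = ["GRN", "autoimmunity", "RNA-seq", "macrophage", "HLA-pep"]
    true_classes = (
        ["true-median-train"] * config.n_true_median_train
        + ["true-median-split"] * config.n_true_median_split
        + ["true-zero"] * config.n_true_zero
        + ["true-exclude"] * config.n_true_exclude
    )
    n_pseudo = config.n_features - len(true_classes)
    if n_pseudo < config.n_signal:
        raise ValueError("not enough pseudo-missing slots for the signal features")
    # signal features stay pseudo-missing so the planted effect survives imputation
    classes = (["pseudo"] * config.n_signal + true_classes
               + ["pseudo"] * (n_pseudo - config.n_signal))
    specs = [
        FeatureSpec(name=names[j], category=categories[j % len(categories)],
                    missingness_class=classes[j])
        for j in range(config.n_features)
    ]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=names)
    if config.missing_rate > 0:
        for j, s in enumerate(specs):
            mask = rng.random(config.n_genes) < config.missing_rate
            df.iloc[mask, j] = np.nan
    features = FeatureTable(df, specs)

    # pathways: random gene sets biased towards graph locality (seeded from
    # a random gene plus neighbours, padded at random)
    pathways = {}
    for p in range(config.n_pathways):
        seed_gene = genes[int(rng.integers(config.n_genes))]
        members = {seed_gene} | set(graph.neighbours(seed_gene))
        others = rng.choice(config.n_genes, size=config.pathway_size, replace=False)
        members |= {genes[i] for i in others}
        pathways[f"PW{p:03d}"] = set(list(members)[: config.pathway_size])
    pathway_set = PathwaySet(pathways)

    # DEG table: Wald statistic tracks propensity, expression independent
    wald = config.deg_alpha * z + rng.normal(0, config.deg_noise_sd, config.n_genes)
    pvals = 2 * stats.norm.sf(np.abs(wald))
    padj = stats.false_discovery_control(pvals, method="bh")
    base_mean = np.exp(rng.normal(3.0, 1.5, config.n_genes))
    degs = pd.DataFrame(
        {"stat": wald, "padj": padj, "baseMean": base_mean},
        index=pd.Index(genes, name="gene"),
    )

    omics = _generate_omics(config, genes, z, rng)

    truth = {
        "signal_features": signal_cols,
        "propensity": {g: float(v) for g, v in zip(genes, z)},
        "positives": sorted(positives),
        "timesliced": sorted(timesliced),
        "homophily": config.homophily,
        "effect_size": config.effect_size,
        "config": asdict(config),
    }
    return SynthBundle(graph=graph, features=features, labels=labels,
                       pathways=pathway_set, degs=degs, omics=omics, truth=truth)


def _generate_omics(config: SynthConfig, genes, z, rng) -> CohortOmics:
    """Patient-level mutation / copy-number / expression data consistent
    with the featurization formulas, on a small gene panel."""
    n_pat = config.n_patients
    patients = [f"P{i:03d}" for i in range(n_pat)]
    response = {p: ("R" if i < n_pat // 2 else "NR") for i, p in enumerate(patients)}
    panel = genes[: min(50, len(genes))]

    mutations: dict[tuple[str, str], list[str]] = {}
    cats = np.array(["LoF", "missense", "other"])
    for p in patients:
        for g in panel:
            draw = rng.random()
            if draw < 0.1:
                mutations[(p, g)] = [str(cats[int(rng.integers(3))])]
    cn = pd.DataFrame(
        rng.choice([1, 2, 2, 2, 3, 4], size=(n_pat, len(panel))).astype(float),
        index=patients, columns=panel,
    )
    expr = pd.DataFrame(
        np.exp(rng.normal(2.0, 1.0, size=(n_pat, len(panel)))),
        index=patients, columns=panel,
    )
    return CohortOmics(response=response, mutations=mutations,
                       copy_number=cn, expression=expr)


def truth(config: SynthConfig, bundle: SynthBundle) -> dict:
    """Ground-truth manifest for parameter-recovery checks; JSON-stable."""
    manifest = dict(bundle.truth)
    manifest["n_genes"] = config.n_genes
    # round-trip guard: everything must be JSON-serializable
    json.loads(json.dumps(manifest))
    return manifest


def write_fixture(bundle: SynthBundle, outdir) -> None:
    """Write the fixture in the exact text formats the loaders consume."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "w") as fh:
        for a, b in sorted(bundle.graph.edges):
            fh.write(f"{a}\t{b}\n")
    bundle.features.values.to_csv(out / "features.tsv", sep="\t")
    specs = {
        s.name: {"category": s.category, "missingness_class": s.missingness_class}
        for s in bundle.features.specs
    }
    (out / "features.json").write_text(json.dumps(specs, indent=1))
    with open(out / "labels.tsv", "w") as fh:
        for g in sorted(bundle.labels.positives):
            fh.write(f"{g}\t{bundle.labels.phases.get(g, 'NA')}\n")
    (out / "timesliced.txt").write_text(
        "\n".join(sorted(bundle.labels.timesliced)) + "\n"
    )
    with open(out / "pathways.gmt", "w") as fh:
        for pid, members in bundle.pathways.items():
            fh.write(pid + "\tsynthetic\t" + "\t".join(sorted(members)) + "\n")
    bundle.degs.to_csv(out / "degs.tsv", sep="\t")
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=1))
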