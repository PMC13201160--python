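"""Per-gene node features from raw cohort inputs.

Each summarizer collapses a patient-level (or sample-level) data modality to
one or a few numbers per gene, stratified by checkpoint-inhibitor response
where the modality is clinical.  All summarizers are optional: precomputed
feature matrices can be supplied to :mod:`midas.graphio` directly.

Response labels are ``"R"`` (radiological responder) and ``"NR"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: Mutation-category weights; ties across calls are broken by this hierarchy.
MUTATION_WEIGHTS = {"LoF": 2.0, "missense": 1.0, "other": 0.0}

#: Genome-wide significance threshold for GWAS SNP associations.
GWAS_P_THRESHOLD = 5e-8

#: The three immuno-oncology-relevant phenotype categories.
GWAS_CATEGORIES = (
    "autoimmune/rheumatic/allergic",
    "blood counts",
    "cytokine/chemokine",
)

#: Floor applied to a total copy number of 0 before taking logs
#: (homozygous deletions; the log is otherwise undefined).
CN_FLOOR = 1e-3


@dataclass
class CohortOmics:
    """Patient-level mutation, copy-number and expression data with
    responder / non-responder annotations.

    ``mutations`` maps (patient, gene) to a list of category calls
    ("LoF", "missense", "other"); multiple calls per gene are resolved by
    the LoF > missense > other hierarchy.  ``copy_number`` and
    ``expression`` are patient x gene DataFrames.
    """

    response: dict[str, str]
    mutations: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    copy_number: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None

    def __post_init__(self):
        bad = set(self.response.values()) - {"R", "NR"}
        if bad:
            raise ValueError(f"unknown response labels: {sorted(bad)}")
        if self.copy_number is not None and (self.copy_number.to_numpy() < 0).any():
            raise ValueError("copy number must be non-negative")

    def patients_by_response(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {"R": [], "NR": []}
        for p, r in self.response.items():
            out[r].append(p)
        return out


@dataclass
class PeptidomeInput:
    """Per-sample gene expression and per-sample peptide q-values.

    ``peptide_q`` is a DataFrame (sample x peptide) of detection q-values,
    ``peptide_gene`` maps peptide -> source gene, ``expression`` is
    sample x gene.
    """

    expression: pd.DataFrame
    peptide_q: pd.DataFrame
    peptide_gene: Mapping[str, str]

    def __post_init__(self):
        q = self.peptide_q.to_numpy(dtype=float)
        finite = q[np.isfinite(q)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("q-values must lie in [0, 1]")


def _resolve_category(calls: list[str]) -> str:
    for cat in ("LoF", "missense", "other"):
        if cat in calls:
            return cat
    raise ValueError(f"unknown mutation categories: {calls}")


def summarize_mutations(omics: CohortOmics) -> pd.DataFrame:
    """Mean weighted mutation burden per gene, per response group.

    Weights: loss of function = 2, missense = 1, otherwise = 0; a patient
    with several calls for the same gene counts once, at the highest
    category.  Returns columns ``mutation_R`` and ``mutation_NR``.
    """
    groups = omics.patients_by_response()
    for r, pats in groups.items():
        if not pats:
            raise ValueError(f"no patients in response class {r!r}")
    genes = sorted({g for (_, g) in omics.mutations})
    out = pd.DataFrame(index=genes, columns=["mutation_R", "mutation_NR"], dtype=float)
    for r, col in (("R", "mutation_R"), ("NR", "mutation_NR")):
        pats = groups[r]
        for g in genes:
            weights = [
                MUTATION_WEIGHTS[_resolve_category(omics.mutations.get((p, g), ["other"]))]
                for p in pats
            ]
            out.loc[g, col] = float(np.mean(weights))
    return out


def log_r(copy_number, dialect: str = "as-printed"):
    """Copy-number representation log[R].

    ``as-printed`` is log2(total copy number) / 2; ``ratio`` is the
    conventional log2(total copy number / 2).  CN = 0 is floored to
    ``CN_FLOOR`` first.
    """
    cn = np.maximum(np.asarray(copy_number, dtype=float), CN_FLOOR)
    if dialect == "as-printed":
        return np.log2(cn) / 2.0
    if dialect == "ratio":
        return np.log2(cn / 2.0)
    raise ValueError(f"unknown log[R] dialect {dialect!r}")


def summarize_copy_number(omics: CohortOmics, dialect: str = "as-printed") -> pd.DataFrame:
    """Median log[R] per gene within each response group
    (columns ``cn_R``, ``cn_NR``)."""
    if omics.copy_number is None:
        raise ValueError("cohort has no copy-number data")
    groups = omics.patients_by_response()
    for r, pats in groups.items():
        if not pats:
            raise ValueError(f"no patients in response class {r!r}")
    lr = pd.DataFrame(
        log_r(omics.copy_number.to_numpy(), dialect=dialect),
        index=omics.copy_number.index,
        columns=omics.copy_number.columns,
    )
    return pd.DataFrame(
        {
            "cn_R": lr.loc[groups["R"]].median(axis=0),
            "cn_NR": lr.loc[groups["NR"]].median(axis=0),
        }
    )


def preprocess_bulk_expression(
    tpm: pd.DataFrame,
    covariates: pd.DataFrame,
    unexpressed_fraction: float = 0.65,
    unexpressed_threshold: float = 0.0,
) -> pd.DataFrame:
    """Filter, quantile-normalize and residualize a patient x gene TPM matrix.

    Genes with expression <= ``unexpressed_threshold`` in at least
    ``unexpressed_fraction`` of patients are removed.  Columns (genes are
    columns after transposition per patient profile) are quantile-normalized
    to the mean sorted profile across patients; then per-gene ordinary
    least squares on the covariate indicator columns removes study / tissue
    effects, with the grand mean added back so feature scales remain
    interpretable.
    """
    if tpm.shape[0] < 2:
        raise ValueError("quantile normalization needs at least 2 patients")
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM must be non-negative")
    frac_zero = (tpm <= unexpressed_threshold).mean(axis=0)
    keep = frac_zero[frac_zero < unexpressed_fraction].index
    x = tpm[keep].to_numpy(dtype=float)

    # quantile normalization across patients: each patient profile gets the
    # mean sorted profile, assigned back through its own ranks (average over
    # ties via rank interpolation on sorted order)
    order = np.argsort(x, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n_p, n_g = x.shape
    col_idx = np.arange(n_g)
    for i in range(n_p):
        ranks[i, order[i]] = col_idx
    mean_sorted = np.sort(x, axis=1).mean(axis=0)
    qn = mean_sorted[ranks]

    # residualize on covariate dummies, add intercept back
    dummies = pd.get_dummies(covariates.loc[tpm.index].astype(str), drop_first=True)
    design = np.column_stack([np.ones(n_p), dummies.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(design, qn, rcond=None)
    resid = qn - design @ beta
    out = resid + qn.mean(axis=0)
    return pd.DataFrame(out, index=tpm.index, columns=keep)


def summarize_expression(expression: pd.DataFrame, response: Mapping[str, str]) -> pd.DataFrame:
    """Median normalized expression per gene within each response group
    (columns ``expr_R``, ``expr_NR``)."""
    groups: dict[str, list[str]] = {"R": [], "NR": []}
    for p in expression.index:
        groups[response[p]].append(p)
    for r, pats in groups.items():
        if not pats:
            raise ValueError(f"no patients in response class {r!r}")
    return pd.DataFrame(
        {
            "expr_R": expression.loc[groups["R"]].median(axis=0),
            "expr_NR": expression.loc[groups["NR"]].median(axis=0),
        }
    )


def peptidome_correlations(pep: PeptidomeInput, q_threshold: float = 0.05) -> pd.Series:
    """Per-gene Pearson correlation between expression and HLA peptide
    presentation across samples.

    Presentation of a gene in a sample = number of its peptides detected at
    q < ``q_threshold`` (all sample HLA molecules pooled).  Genes never
    presented, or with a zero-variance series on either side, are returned
    as NaN for downstream true-median imputation.
    """
    if pep.expression.shape[0] < 3:
        raise ValueError("need at least 3 samples for peptidome correlations")
    samples = pep.expression.index
    detected = (pep.peptide_q.loc[samples] < q_threshold)
    genes = sorted(set(pep.peptide_gene.values()) & set(pep.expression.columns))
    counts = pd.DataFrame(0, index=samples, columns=genes, dtype=float)
    for peptide in detected.columns:
        g = pep.peptide_gene.get(peptide)
        if g in counts.columns:
            counts[g] += detected[peptide].astype(float)
    out = pd.Series(np.nan, index=pd.Index(genes, name="gene"))
    for g in genes:
        x = pep.expression[g].to_numpy(dtype=float)
        y = counts[g].to_numpy()
        if y.sum() == 0 or np.std(y) == 0 or np.std(x) == 0:
            continue
        out[g] = stats.pearsonr(x, y).statistic
    return out


def count_gwas(snps: pd.DataFrame) -> pd.DataFrame:
    """Count genome-wide-significant, non-intergenic SNP associations per
    (gene, phenotype category).

    ``snps`` columns: snp, gene, category, p, intergenic.  Distinct SNPs are
    counted once per (gene, category).  Genes absent get 0 downstream
    (pseudo-missing).
    """
    bad = set(snps["category"]) - set(GWAS_CATEGORIES)
    if bad:
        raise ValueError(f"unknown GWAS categories: {sorted(bad)}")
    ok = snps[(snps["p"] <= GWAS_P_THRESHOLD) & (~snps["intergenic"].astype(bool))]
    counts = (
        ok.drop_duplicates(["snp", "gene", "category"])
        .groupby(["gene", "category"])
        .size()
        .unstack(fill_value=0)
    )
    return counts.reindex(columns=list(GWAS_CATEGORIES), fill_value=0)


def transform_crispr(mageck: pd.DataFrame) -> pd.DataFrame:
    """-log10 of MAGeCK scores, one feature per (cell line, direction).

    ``mageck`` columns: gene, cell_line, direction ("evading"/"sensitized"),
    score in (0, 1].  Genes absent from a screen stay NaN and are treated as
    true-exclude downstream.
    """
    bad = set(mageck["direction"]) - {"evading", "sensitized"}
    if bad:
        raise ValueError(f"unknown CRISPR screen directions: {sorted(bad)}")
    if (mageck["score"] <= 0).any():
        raise ValueError("MAGeCK scores must be in (0, 1]")
    df = mageck.copy()
    df["feature"] = "crispr_" + df["cell_line"].astype(str) + "_" + df["direction"]
    df["value"] = -np.log10(df["score"].astype(float))
    return df.pivot_table(index="gene", columns="feature", values="value")
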