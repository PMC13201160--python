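"""Scoring metrics, statistical tests and the in-silico validation tasks.

Three validation procedures probe a fitted ranking of genes:

* time-sliced test — are targets that entered trials after the label freeze
  scored above size-matched random gene sets?
* phase ranking — do approved targets outscore those in development?
* DEG recovery — do the top predictions recover checkpoint-inhibitor
  response differentially expressed genes beyond expression-matched chance?

Empirical P values follow the as-printed resampling definition
p = #(null draws >= |observed|) / #draws; an optional add-one correction
((r + 1) / (n + 1)) is available behind a flag and off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ----------------------------------------------------------------------
# ROC-AUC and comparisons


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted 1/2 (Mann-Whitney identity)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    r_pos = ranks[labels == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(scores, labels):
    """DeLong structural components for a single ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return auc, v10, v01, s10 / m + s01 / n


def compare_roc(
    scores_a,
    scores_b,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> float:
    """Two-sided p-value for a difference between two paired ROC curves.

    ``delong`` uses the covariance of the placement values; ``bootstrap``
    uses a percentile bootstrap of the AUC difference over genes.
    Degenerate variance (e.g. identical score vectors) yields p = 1 with a
    warning.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if method == "delong":
        auc_a, v10a, v01a, _ = _delong_variance(scores_a, labels)
        auc_b, v10b, v01b, _ = _delong_variance(scores_b, labels)
        m, n = len(v10a), len(v01a)
        # covariance of paired curves
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
        var = (
            s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
            + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
        )
        if var <= 0:
            warnings.warn("degenerate DeLong variance; returning p = 1")
            return 1.0
        z = (auc_a - auc_b) / np.sqrt(var)
        return float(2 * stats.norm.sf(abs(z)))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        n_obs = len(labels)
        deltas = np.empty(n_boot)
        obs = roc_auc(scores_a, labels) - roc_auc(scores_b, labels)
        for i in range(n_boot):
            while True:
                idx = rng.integers(0, n_obs, size=n_obs)
                if 0 < labels[idx].sum() < n_obs:
                    break
            deltas[i] = roc_auc(scores_a[idx], labels[idx]) - roc_auc(
                scores_b[idx], labels[idx]
            )
        if np.all(deltas == deltas[0]) and deltas[0] == obs:
            warnings.warn("degenerate bootstrap distribution; returning p = 1")
            return 1.0
        # two-sided: twice the smaller tail of the bootstrap distribution
        # around a zero difference
        p_low = np.mean(deltas <= 0)
        p_high = np.mean(deltas >= 0)
        return float(min(1.0, 2 * min(p_low, p_high)))
    raise ValueError(f"unknown method {method!r}")


# ----------------------------------------------------------------------
# resampling machinery


@dataclass
class NullDistribution:
    """Null draws with a descriptor of how they were generated."""

    draws: np.ndarray
    resampled: str
    seed: int | None = None

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)

    @property
    def n(self) -> int:
        return len(self.draws)


def empirical_p(observed: float, null: NullDistribution | np.ndarray, add_one: bool = False) -> float:
    """p = #(draws >= |observed|) / #draws, exactly as the resampling
    definition of a p-value; ``add_one`` applies (r + 1) / (n + 1)."""
    draws = null.draws if isinstance(null, NullDistribution) else np.asarray(null, dtype=float)
    if len(draws) < 1:
        raise ValueError("need at least one null draw")
    r = int(np.sum(draws >= abs(observed)))
    if add_one:
        return (r + 1) / (len(draws) + 1)
    return r / len(draws)


# ----------------------------------------------------------------------
# rank tests


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (normal approximation, continuity and tie
    correction).  Returns (U, p)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks on ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank_exact(differences) -> tuple[float, float]:
    """Exact two-sided paired Wilcoxon signed-rank test by full enumeration.

    All 2^n sign assignments of the (average-tied) ranks of |d_i| are
    enumerated; W is the sum of positive ranks; the two-sided p doubles the
    smaller tail probability of the observed W, capped at 1.  Intended for
    small n (<= ~25 non-zero differences).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n > 25:
        raise ValueError("exact enumeration limited to n <= 25")
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())

    total = 2 ** n
    # distribution of W over all sign assignments via subset-sum convolution
    # on doubled ranks (handles half-integer average ranks exactly)
    scaled = np.round(ranks * 2).astype(int)
    max_sum = int(scaled.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    assert counts.sum() == total
    w_scaled = int(round(w_obs * 2))
    lower = counts[: w_scaled + 1].sum() / total
    upper = counts[w_scaled:].sum() / total
    p = 2.0 * min(lower, upper)
    return w_obs, float(min(1.0, p))


# ----------------------------------------------------------------------
# validation tasks


def timesliced_test(
    predictions: pd.Series,
    timesliced,
    n_random: int = 1000,
    seed: int | None = None,
    mw_comparand: str = "null-means",
) -> dict:
    """Score genes that entered trials after the label freeze against
    size-matched random gene sets.

    The null is the mean prediction across ``n_random`` uniformly sampled
    size-matched sets drawn from ALL scored genes (time-sliced genes are not
    excluded from the sampling, to avoid deflating the null).  Returns the
    empirical p, a Mann-Whitney p (time-sliced scores vs the null means by
    default, or vs all other gene scores with ``mw_comparand="other-genes"``)
    and the null distribution.
    """
    timesliced = sorted(set(timesliced))
    if not timesliced:
        raise ValueError("empty time-sliced set")
    missing = [g for g in timesliced if g not in predictions.index]
    if missing:
        raise ValueError(f"time-sliced genes not scored: {missing[:5]}")
    rng = np.random.default_rng(seed)
    scores = predictions.to_numpy(dtype=float)
    ts_scores = predictions.loc[timesliced].to_numpy(dtype=float)
    observed = float(ts_scores.mean())
    k = len(timesliced)
    draws = np.array(
        [scores[rng.choice(len(scores), size=k, replace=False)].mean() for _ in range(n_random)]
    )
    null = NullDistribution(draws, resampled=f"{n_random} size-matched gene sets (k={k})", seed=seed)
    if mw_comparand == "null-means":
        _, mw_p = mann_whitney_u(ts_scores, draws)
    elif mw_comparand == "other-genes":
        others = predictions.drop(index=timesliced).to_numpy(dtype=float)
        _, mw_p = mann_whitney_u(ts_scores, others)
    else:
        raise ValueError(f"unknown comparand {mw_comparand!r}")
    return {
        "observed_mean": observed,
        "empirical_p": empirical_p(observed, null),
        "mannwhitney_p": mw_p,
        "null": null,
    }


def phase_ranking_test(
    predictions: pd.Series,
    phases: dict[str, str],
    timesliced=(),
    recategorize_timesliced: bool = False,
) -> dict:
    """Compare prediction distributions across clinical-phase groups.

    Groups are approved, phases I-III (in development) and NA/non-target.
    Time-sliced genes are excluded by default; with
    ``recategorize_timesliced`` they join the in-development group instead.
    Returns the Kruskal-Wallis p across groups, the Mann-Whitney p for
    approved vs in-development, and group means with standard errors.
    """
    timesliced = set(timesliced)
    groups: dict[str, list[float]] = {"approved": [], "in development": [], "non-target": []}
    for g in predictions.index:
        if g in timesliced:
            if recategorize_timesliced:
                groups["in development"].append(float(predictions[g]))
            continue
        phase = phases.get(g, "NA")
        if phase == "approved":
            groups["approved"].append(float(predictions[g]))
        elif phase.startswith("phase"):
            groups["in development"].append(float(predictions[g]))
        else:
            groups["non-target"].append(float(predictions[g]))
    non_empty = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(non_empty) < 2:
        raise ValueError("phase ranking needs at least two non-empty groups")
    _, kw_p = kruskal_wallis(*non_empty.values())
    mw_p = None
    if groups["approved"] and groups["in development"]:
        _, mw_p = mann_whitney_u(groups["approved"], groups["in development"])
    else:
        warnings.warn("empty approved or in-development group; skipping Mann-Whitney")
    summary = {
        k: {
            "n": len(v),
            "mean": float(np.mean(v)) if v else float("nan"),
            "se": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan"),
        }
        for k, v in groups.items()
    }
    return {"kruskal_p": kw_p, "mannwhitney_approved_vs_dev_p": mw_p, "groups": summary}


def _expression_strata(mean_expression: pd.Series, n_strata: int) -> pd.Series:
    """Assign genes to (roughly decile) strata of mean expression, merging
    adjacent strata that end up too small to sample from."""
    ranks = mean_expression.rank(method="first")
    strata = pd.cut(ranks, bins=n_strata, labels=False)
    return pd.Series(strata, index=mean_expression.index)


def deg_recovery_test(
    predictions: pd.Series,
    degs: pd.DataFrame,
    top_n: int = 200,
    n_random: int = 1000,
    n_strata: int = 10,
    padj_threshold: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Overlap of the top predictions with differentially expressed genes,
    against an expression-stratified resampling null.

    ``degs`` columns: ``stat`` (Wald), ``padj``, ``baseMean``.  The null
    samples gene sets matching the top set's distribution across
    mean-expression strata (deciles by default).
    """
    common = [g for g in predictions.index if g in degs.index]
    preds = predictions.loc[common].sort_values(ascending=False)
    top = list(preds.index[:top_n])
    deg_set = set(degs.index[degs["padj"] < padj_threshold]) & set(common)
    observed = len(set(top) & deg_set)

    strata = _expression_strata(degs.loc[common, "baseMean"], n_strata)
    rng = np.random.default_rng(seed)
    by_stratum: dict[int, np.ndarray] = {
        s: np.array(strata.index[strata == s]) for s in strata.unique()
    }
    # required draw counts per stratum, matching the top set's profile;
    # strata with too few genes donate to their neighbour
    need = strata.loc[top].value_counts().to_dict()
    merged_need: dict[int, int] = {}
    for s in sorted(need):
        if len(by_stratum.get(s, ())) < need[s]:
            warnings.warn(f"stratum {s} too small; merging into neighbour")
            neighbour = s + 1 if s + 1 in by_stratum else s - 1
            merged_need[neighbour] = merged_need.get(neighbour, 0) + need[s]
        else:
            merged_need[s] = merged_need.get(s, 0) + need[s]
    draws = np.empty(n_random)
    for i in range(n_random):
        sampled: list[str] = []
        for s, k in merged_need.items():
            pool = by_stratum[s]
            sampled.extend(pool[rng.choice(len(pool), size=min(k, len(pool)), replace=False)])
        draws[i] = len(set(sampled) & deg_set)
    null = NullDistribution(
        draws, resampled=f"{n_random} expression-stratified size-matched sets", seed=seed
    )
    return {
        "overlap": observed,
        "n_deg": len(deg_set),
        "empirical_p": empirical_p(observed, null),
        "null": null,
    }


def ranked_deg_correlation(
    predictions: pd.Series,
    degs: pd.DataFrame,
    top: int = 1000,
    bin_size: int = 200,
) -> pd.DataFrame:
    """Spearman correlation between predictions and the DEG Wald statistic
    within consecutive rank bins of the top predictions."""
    common = [g for g in predictions.index if g in degs.index]
    if top > len(common):
        raise ValueError(f"top={top} exceeds the {len(common)} scored genes with DEG data")
    preds = predictions.loc[common].sort_values(ascending=False).iloc[:top]
    rows = []
    for start in range(0, top, bin_size):
        chunk = preds.iloc[start : start + bin_size]
        if len(chunk) < 3:
            continue
        rho, p = spearman(chunk.to_numpy(), degs.loc[chunk.index, "stat"].to_numpy())
        rows.append({"bin_start": start + 1, "bin_end": start + len(chunk), "rho": rho, "p": p})
    return pd.DataFrame(rows)
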