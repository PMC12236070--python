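"""Group-level statistics for features x cells matrices.

Powers the usual single-cell summaries: per-group mean/median, the
heatmap convention z-score (per feature, standardize group means across
groups), one-vs-rest log fold change and Welch t, proportion of positive
cells, waterfall rankings between two groups, Broad-style GSEA running
scores with a Kolmogorov-Smirnov p-value, and two-group per-feature
significance tests with star codes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DataError, UsageError
from .geneset_db import GeneSet

__all__ = [
    "GroupStats",
    "GseaResult",
    "group_metric",
    "proportion_positive",
    "waterfall_rank",
    "gsea_running_score",
    "two_group_feature_test",
    "stars",
]

_METRICS = ("mean", "median", "zscore", "logfc", "tscore", "prop_positive")

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class GroupStats:
    """Features x groups matrix of one named metric."""

    values: pd.DataFrame  # index = feature ids, columns = group ids
    metric: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise UsageError(f"unknown metric {self.metric!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def group_ids(self) -> list[str]:
        return list(self.values.columns)


def _as_frame(matrix, feature_ids=None, cell_ids=None) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    matrix = np.asarray(matrix, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(matrix.shape[0])]
    if cell_ids is None:
        cell_ids = list(range(matrix.shape[1]))
    return pd.DataFrame(matrix, index=feature_ids, columns=cell_ids)


def _check_labels(df: pd.DataFrame, labels) -> pd.Series:
    labels = pd.Series(np.asarray(labels), index=df.columns)
    if labels.isna().any():
        raise DataError("every cell must carry a group label")
    return labels


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row with sample sd (ddof=1); zero-sd rows -> 0."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    sd = sd.mask(sd <= 1e-12 * (mu.abs() + 1.0))  # near-constant rows -> NaN
    z = values.sub(mu, axis=0).div(sd, axis=0)
    return z.fillna(0.0)


def group_metric(matrix, labels, metric: str, pseudocount: float = 1.0,
                 feature_ids=None) -> GroupStats:
    """Per-group summary of a features x cells matrix.

    mean/median: plain group summaries. zscore: z across the group means
    per feature. logfc: log2((mean_in + p) / (mean_rest + p)) one-vs-rest
    with pseudocount p. tscore: Welch t statistic one-vs-rest.
    """
    if metric not in ("mean", "median", "zscore", "logfc", "tscore"):
        raise UsageError(f"group_metric does not compute {metric!r}")
    if metric == "logfc" and pseudocount <= 0:
        raise UsageError("pseudocount must be > 0")
    df = _as_frame(matrix, feature_ids)
    labels = _check_labels(df, labels)
    groups = sorted(pd.unique(labels), key=str)
    for g in groups:
        if (labels == g).sum() == 0:
            raise DataError(f"group {g!r} has no cells")
    means = pd.DataFrame(
        {g: df.loc[:, (labels == g).to_numpy()].mean(axis=1) for g in groups}
    )
    if metric == "mean":
        values = means
    elif metric == "median":
        values = pd.DataFrame(
            {g: df.loc[:, (labels == g).to_numpy()].median(axis=1) for g in groups}
        )
    elif metric == "zscore":
        values = zscore_rows(means)
    elif metric == "logfc":
        cols = {}
        for g in groups:
            rest = df.loc[:, (labels != g).to_numpy()].mean(axis=1)
            cols[g] = np.log2((means[g] + pseudocount) / (rest + pseudocount))
        values = pd.DataFrame(cols)
    else:  # tscore, Welch one-vs-rest
        cols = {}
        for g in groups:
            in_mask = (labels == g).to_numpy()
            a, b = df.loc[:, in_mask], df.loc[:, ~in_mask]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False).statistic
            cols[g] = np.nan_to_num(t, nan=0.0)
        values = pd.DataFrame(cols, index=df.index)
    return GroupStats(values=values, metric=metric,
                      params={"pseudocount": pseudocount, "reference": "one_vs_rest"})


def proportion_positive(matrix, labels, threshold: float = 0.0,
                        feature_ids=None) -> GroupStats:
    """Fraction of cells per group with value strictly above threshold."""
    df = _as_frame(matrix, feature_ids)
    labels = _check_labels(df, labels)
    groups = sorted(pd.unique(labels), key=str)
    cols = {}
    for g in groups:
        mask = (labels == g).to_numpy()
        if mask.sum() == 0:
            raise DataError(f"group {g!r} has no cells")
        cols[g] = (df.loc[:, mask] > threshold).mean(axis=1)
    return GroupStats(values=pd.DataFrame(cols), metric="prop_positive",
                      params={"threshold": threshold})


def waterfall_rank(matrix, labels, group_a, group_b, metric: str = "logfc",
                   top_n: int = 20, pseudocount: float = 1.0,
                   feature_ids=None) -> pd.DataFrame:
    """Rank features by a two-group contrast for a waterfall plot.

    Returns a DataFrame sorted by metric descending with columns
    ``value`` and ``labeled`` — the label mask marks the top_n features
    by |metric| (ties broken by feature id).
    """
    if metric not in ("mean_diff", "logfc", "tscore"):
        raise UsageError(f"unknown waterfall metric {metric!r}")
    df = _as_frame(matrix, feature_ids)
    labels = _check_labels(df, labels)
    for g in (group_a, group_b):
        if g not in set(labels):
            raise DataError(f"unknown group id {g!r}")
    a = df.loc[:, (labels == group_a).to_numpy()]
    b = df.loc[:, (labels == group_b).to_numpy()]
    if metric == "mean_diff":
        value = a.mean(axis=1) - b.mean(axis=1)
    elif metric == "logfc":
        value = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False).statistic
        value = pd.Series(np.nan_to_num(t, nan=0.0), index=df.index)
    out = pd.DataFrame({"value": value})
    out = out.sort_values(["value"], ascending=False, kind="stable")
    out = out.loc[sorted(out.index, key=lambda i: (-out.loc[i, "value"], str(i)))]
    by_abs = sorted(out.index, key=lambda i: (-abs(out.loc[i, "value"]), str(i)))
    labeled = set(by_abs[: min(top_n, len(by_abs))])
    out["labeled"] = [i in labeled for i in out.index]
    return out


@dataclass
class GseaResult:
    """Broad-style running enrichment score plus a KS rank test."""

    es: float
    running_curve: np.ndarray  # length G+1, starts and ends at 0
    leading_edge: list[str]
    ks_stat: float
    p_value: float


def gsea_running_score(ranked_metric: pd.Series, gene_set: GeneSet,
                       weight_p: float = 1.0) -> GseaResult:
    """Running enrichment score over a descending-ordered gene statistic.

    Walking down the ranking, a set member at position i adds
    |stat_i|^p / sum_hits |stat|^p and a non-member subtracts 1/(G - m).
    ES is the signed maximal deviation; the leading edge collects the
    members up to (for ES > 0) or after (ES < 0) the extremum. The
    p-value is a two-sample KS test comparing member vs non-member rank
    positions (asymptotic).
    """
    if not isinstance(ranked_metric, pd.Series):
        raise UsageError("ranked_metric must be a pandas Series indexed by gene")
    genes = list(ranked_metric.index)
    G = len(genes)
    members = set(gene_set.genes) & set(genes)
    m = len(members)
    if m == 0:
        raise DataError(f"gene set {gene_set.id!r} shares no genes with the ranking")
    if m == G:
        raise DataError("gene set covers the whole ranking; no background remains")
    stats = ranked_metric.to_numpy(dtype=float)
    hit = np.array([g in members for g in genes])
    w = np.abs(stats) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member stats are 0 under p>0: fall back to equal weights
        hit_w = hit.astype(float)
        total = hit_w.sum()
    steps = np.where(hit, hit_w / total, -1.0 / (G - m))
    curve = np.concatenate([[0.0], np.cumsum(steps)])
    curve[-1] = 0.0 if abs(curve[-1]) < 1e-12 else curve[-1]
    ext = int(np.argmax(np.abs(curve)))
    es = float(curve[ext])
    if es >= 0:
        leading = [g for i, g in enumerate(genes) if hit[i] and i < ext]
    else:
        leading = [g for i, g in enumerate(genes) if hit[i] and i >= ext]
    positions = np.arange(1, G + 1)
    ks = scipy.stats.ks_2samp(positions[hit], positions[~hit], method="asymp")
    return GseaResult(es=es, running_curve=curve, leading_edge=leading,
                      ks_stat=float(ks.statistic), p_value=float(ks.pvalue))


def stars(p: float) -> str:
    """Significance stars: ns, *, **, ***, **** at 0.05/0.01/0.001/0.0001."""
    for threshold, code in STAR_THRESHOLDS:
        if p < threshold:
            return code
    return "ns"


def two_group_feature_test(matrix, labels, group_a, group_b,
                           test: str = "wilcoxon", feature_ids=None) -> pd.DataFrame:
    """Per-feature two-group test with star codes.

    ``wilcoxon``: rank-sum via the Mann-Whitney U normal approximation
    (continuity- and tie-corrected). ``welch_t``: unequal-variance t.
    Features constant across both groups get p = 1 with a warning.
    """
    if test not in ("wilcoxon", "welch_t"):
        raise UsageError(f"unknown test {test!r}")
    df = _as_frame(matrix, feature_ids)
    labels = _check_labels(df, labels)
    a = df.loc[:, (labels == group_a).to_numpy()].to_numpy()
    b = df.loc[:, (labels == group_b).to_numpy()].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DataError("both groups need >= 2 cells")
    constant = (df.max(axis=1) - df.min(axis=1)).to_numpy() == 0
    if test == "wilcoxon":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = scipy.stats.mannwhitneyu(a, b, axis=1, method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    else:
        res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant features set to p = 1",
                      stacklevel=2)
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    return pd.DataFrame(
        {"p_value": p, "stars": [stars(x) for x in p]}, index=df.index
    )
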