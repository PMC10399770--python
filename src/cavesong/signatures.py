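"""Population-signature statistics.

Whether each cave (or lab line) carries a specific acoustic signature is
assessed the way the field does: assumption checks (normality,
homoscedasticity), rank-based group comparisons (Kruskal-Wallis with Dunn's
post hoc z-tests), a PCA acoustic space with 95% confidence ellipses per
group, permuted discriminant function analysis (pDFA: leave-one-out LDA
reclassification whose significance comes from a label-permutation null),
and a hierarchical clustering tree of per-group acoustic medians that can
be projected onto cave geographical coordinates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .features import FeatureTable

__all__ = [
    "AssumptionFlags",
    "GroupComparison",
    "AcousticSpace",
    "PDFAResult",
    "GeoClustering",
    "test_assumptions",
    "compare_groups",
    "acoustic_space",
    "pdfa",
    "geo_cluster",
]

ALPHA = 0.05
#: Total sample size at or below which the Kruskal-Wallis p-value comes from
#: full enumeration of the permutation distribution of H.
EXACT_KW_MAX_N = 10

ADJUST_METHODS = {"bonferroni": "bonferroni", "holm": "holm",
                  "bh": "fdr_bh", "none": None}


# ---------------------------------------------------------------------------
# assumption checks


@dataclass
class AssumptionFlags:
    """Normality (Lilliefors-corrected Kolmogorov-Smirnov, per group) and
    homoscedasticity (Bartlett) checks at ``alpha``."""

    ks_pvalues: dict[str, float]
    bartlett_p: float
    alpha: float = ALPHA
    degenerate: Optional[str] = None
    normality_rejected: dict[str, bool] = field(init=False)
    any_normality_rejected: bool = field(init=False)
    heteroscedastic: bool = field(init=False)

    def __post_init__(self) -> None:
        self.normality_rejected = {g: p < self.alpha
                                   for g, p in self.ks_pvalues.items()}
        self.any_normality_rejected = any(self.normality_rejected.values())
        self.heteroscedastic = (self.bartlett_p < self.alpha
                                or self.degenerate is not None)


def test_assumptions(table: FeatureTable, feature: str,
                     alpha: float = ALPHA) -> AssumptionFlags:
    """Per-group KS (Lilliefors) normality p-values and one Bartlett test."""
    groups = table.group_values(feature)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, x in groups.items():
        if x.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 rows")
    ks_p = {}
    degenerate = None
    for g, x in groups.items():
        if np.std(x) == 0:
            ks_p[g] = 0.0
            degenerate = f"group {g!r} has zero variance"
        else:
            _, p = lilliefors(x, dist="norm")
            ks_p[g] = float(p)
    if degenerate is None:
        _, bartlett_p = stats.bartlett(*groups.values())
        if math.isnan(bartlett_p):
            bartlett_p, degenerate = 0.0, "Bartlett undefined"
    else:
        bartlett_p = 0.0
    return AssumptionFlags(ks_pvalues=ks_p, bartlett_p=float(bartlett_p),
                           alpha=alpha, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def _kw_h(ranks: np.ndarray, labels: np.ndarray, k: int,
          tie_factor: float) -> float:
    """Tie-corrected Kruskal-Wallis H for pooled ranks with group labels."""
    n = ranks.size
    h = 0.0
    for g in range(k):
        rg = ranks[labels == g]
        h += rg.sum() ** 2 / rg.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def _exact_kw_p(ranks: np.ndarray, sizes: Sequence[int],
                h_obs: float, tie_factor: float) -> float:
    """Exact permutation p-value of H by full enumeration of the distinct
    assignments of observations to groups."""
    n = ranks.size
    k = len(sizes)
    count = 0
    total = 0
    labels = np.empty(n, dtype=int)

    def assignments(pool: tuple[int, ...], gi: int):
        nonlocal count, total
        if gi == k - 1:
            labels[list(pool)] = gi
            total += 1
            if _kw_h(ranks, labels, k, tie_factor) >= h_obs - 1e-12:
                count += 1
            return
        for chosen in itertools.combinations(pool, sizes[gi]):
            labels[list(chosen)] = gi
            rest = tuple(i for i in pool if i not in chosen)
            assignments(rest, gi + 1)

    assignments(tuple(range(n)), 0)
    return count / total


@dataclass
class GroupComparison:
    """Kruskal-Wallis result for one feature, with Dunn pairwise post hocs."""

    feature: str
    h_statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float]
    pairwise_unadjusted: dict[tuple[str, str], float]
    assumption_flags: Optional[AssumptionFlags]
    exact: bool
    adjust: str


def compare_groups(table: FeatureTable, feature: str,
                   adjust: str = "bonferroni",
                   check_assumptions: bool = True,
                   exact_max_n: int = EXACT_KW_MAX_N) -> GroupComparison:
    """Kruskal-Wallis test across groups followed by Dunn's post hoc z-tests.

    The H statistic is tie-corrected; its p-value comes from the chi-square
    approximation, or from full enumeration of the permutation distribution
    when the pooled sample size is at most ``exact_max_n``.  Dunn's pairwise
    z-statistics use the tie-corrected rank variance, with the configured
    multiplicity adjustment (``bonferroni`` default, ``holm``, ``bh`` or
    ``none``).  Everything is rank-based, hence invariant under monotone
    transformations of the feature.
    """
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {sorted(ADJUST_METHODS)}")
    groups = table.group_values(feature)
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if groups[g].size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 rows")
    samples = [groups[g] for g in names]
    pooled = np.concatenate(samples)
    n = pooled.size
    sizes = [s.size for s in samples]
    labels = np.repeat(np.arange(len(names)), sizes)
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts ** 3 - tie_counts))
    tie_factor = 1.0 - tie_sum / (n ** 3 - n)

    h = _kw_h(ranks, labels, len(names), tie_factor)
    exact = n <= exact_max_n
    if exact:
        p = _exact_kw_p(ranks, sizes, h, tie_factor)
    elif tie_factor == 0:  # all values identical
        p = 1.0
    else:
        p = float(stats.chi2.sf(h, df=len(names) - 1))
        p = max(p, np.finfo(float).tiny)

    # Dunn's z-tests on mean ranks with tie-corrected variance
    mean_ranks = {g: float(ranks[labels == i].mean())
                  for i, g in enumerate(names)}
    var_term = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        na, nb = groups[a].size, groups[b].size
        se = math.sqrt(var_term * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw.append(2.0 * stats.norm.sf(abs(z)))
    method = ADJUST_METHODS[adjust]
    if method is None or not raw:
        adj = list(raw)
    else:
        adj = list(multipletests(raw, method=method)[1])
    flags = test_assumptions(table, feature) if check_assumptions else None
    return GroupComparison(
        feature=feature, h_statistic=float(h), p_value=float(min(p, 1.0)),
        pairwise=dict(zip(pairs, adj)),
        pairwise_unadjusted=dict(zip(pairs, raw)),
        assumption_flags=flags, exact=exact, adjust=adjust)


# ---------------------------------------------------------------------------
# PCA acoustic space


@dataclass
class GroupEllipse:
    """Confidence ellipse of one group's scores in the first two axes."""

    center: np.ndarray
    covariance: np.ndarray
    confidence: float

    @property
    def mahalanobis_radius2(self) -> float:
        return float(stats.chi2.ppf(self.confidence, df=2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        vi = np.linalg.inv(self.covariance)
        m2 = np.einsum("ij,jk,ik->i", d, vi, d)
        return m2 <= self.mahalanobis_radius2

    def boundary(self, n: int = 200) -> np.ndarray:
        theta = np.linspace(0, 2 * np.pi, n)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        lam, vec = np.linalg.eigh(self.covariance)
        radius = math.sqrt(self.mahalanobis_radius2)
        return (self.center[:, None]
                + radius * vec @ (np.sqrt(lam)[:, None] * circle)).T


@dataclass
class AcousticSpace:
    """Events projected on the principal axes of the (standardized)
    acoustic parameters, with per-group confidence ellipses."""

    scores: pd.DataFrame  # pc1..pcK columns + group
    loadings: pd.DataFrame  # features x axes
    explained_variance: np.ndarray  # fraction per returned axis
    ellipses: dict[str, GroupEllipse]
    features: list[str]

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def coordinates(self) -> np.ndarray:
        return self.scores[[f"pc{i + 1}" for i in range(self.n_axes)]
                           ].to_numpy(float)


def acoustic_space(table: FeatureTable, n_axes: int = 2,
                   confidence: float = 0.95,
                   features: Optional[Sequence[str]] = None,
                   standardize: bool = True) -> AcousticSpace:
    """PCA of the feature table (correlation mode by default: per-column
    z-scores), with per-group ``confidence`` ellipses on the first two axes.

    Constant feature columns are dropped with a warning.  Axes are
    orthonormal; scores have zero mean per axis; explained-variance
    fractions are non-increasing and sum to at most 1.
    """
    names = list(features or table.feature_names)
    X = table.values(names)
    if X.shape[0] < len(names):
        raise ValueError("need at least as many rows as features")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        dropped = [n for n, s in zip(names, sd) if s == 0]
        warnings.warn(f"dropping constant feature columns {dropped}")
        names = [n for n, s in zip(names, sd) if s > 0]
        X = table.values(names)
        sd = X.std(axis=0, ddof=0)
    centered = X - X.mean(axis=0)
    Z = centered / sd if standardize else centered
    n_axes = min(n_axes, Z.shape[1])

    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    scores_full = u * s
    var = s ** 2
    explained = var / var.sum()

    axes = [f"pc{i + 1}" for i in range(n_axes)]
    scores = pd.DataFrame(scores_full[:, :n_axes], columns=axes)
    scores["group"] = table.df["group"].to_numpy()
    loadings = pd.DataFrame(vt[:n_axes].T, index=names, columns=axes)

    ellipses = {}
    if n_axes >= 2:
        for g, sub in scores.groupby("group", observed=True):
            pts = sub[["pc1", "pc2"]].to_numpy(float)
            if pts.shape[0] >= 3:
                ellipses[g] = GroupEllipse(
                    center=pts.mean(axis=0),
                    covariance=np.cov(pts, rowvar=False),
                    confidence=confidence)
    return AcousticSpace(scores=scores, loadings=loadings,
                         explained_variance=explained[:n_axes],
                         ellipses=ellipses, features=names)


# ---------------------------------------------------------------------------
# pDFA


def _loo_lda_predict(X: np.ndarray, yi: np.ndarray, k: int) -> tuple[np.ndarray, bool]:
    """Leave-one-out linear-discriminant predictions.

    Refitting for each held-out sample uses a rank-one downdate of the
    pooled within-class scatter (Sherman-Morrison); a singular scatter
    triggers ridge regularization (flagged in the result).
    """
    n, d = X.shape
    counts = np.bincount(yi, minlength=k).astype(float)
    means = np.vstack([X[yi == c].mean(axis=0) for c in range(k)])
    D = X - means[yi]
    S = D.T @ D
    regularized = False
    lam = 0.0
    for _ in range(2):
        try:
            A = np.linalg.inv(S + lam * np.eye(d))
            if np.linalg.cond(S + lam * np.eye(d)) < 1e12:
                break
        except np.linalg.LinAlgError:
            pass
        lam = 1e-6 * np.trace(S) / d + 1e-12
        regularized = True
    else:
        A = np.linalg.inv(S + lam * np.eye(d))

    AM = means @ A  # (k, d): rows are A @ mu_c (A symmetric)
    preds = np.empty(n, dtype=int)
    factor = max(n - 1 - k, 1)
    for j in range(n):
        c = yi[j]
        nc = counts[c]
        a = nc / (nc - 1.0)
        dv = D[j]
        Ad = A @ dv
        denom = 1.0 - a * float(dv @ Ad)
        if denom <= 1e-10 or nc < 2:
            # degenerate downdate: direct refit without sample j
            mask = np.ones(n, dtype=bool)
            mask[j] = False
            preds[j] = _direct_lda_predict_one(
                X[mask], yi[mask], k, X[j], lam)
            continue
        # Sherman-Morrison inverse of the downdated scatter
        def sinv(v: np.ndarray) -> np.ndarray:
            return A @ v + a * Ad * float(dv @ (A @ v)) / denom

        mu_eff = means.copy()
        mu_eff[c] = means[c] - dv / (nc - 1.0)
        pri = counts.copy()
        pri[c] -= 1.0
        pri /= pri.sum()
        best, best_score = 0, -np.inf
        x = X[j]
        for g in range(k):
            w = sinv(mu_eff[g])
            score = factor * (float(x @ w) - 0.5 * float(mu_eff[g] @ w))
            score += math.log(pri[g]) if pri[g] > 0 else -np.inf
            if score > best_score:
                best, best_score = g, score
        preds[j] = best
    return preds, regularized


def _direct_lda_predict_one(Xt: np.ndarray, yt: np.ndarray, k: int,
                            x: np.ndarray, lam: float) -> int:
    d = Xt.shape[1]
    counts = np.bincount(yt, minlength=k).astype(float)
    means = np.vstack([Xt[yt == c].mean(axis=0) if counts[c] > 0 else
                       np.zeros(d) for c in range(k)])
    D = Xt - means[yt]
    S = D.T @ D + (lam + 1e-12) * np.eye(d)
    A = np.linalg.inv(S)
    pri = counts / counts.sum()
    factor = max(Xt.shape[0] - k, 1)
    scores = [factor * (float(x @ (A @ means[g]))
                        - 0.5 * float(means[g] @ (A @ means[g])))
              + (math.log(pri[g]) if pri[g] > 0 else -np.inf)
              for g in range(k)]
    return int(np.argmax(scores))


@dataclass
class PDFAResult:
    """Permuted discriminant function analysis result."""

    confusion: pd.DataFrame  # rows: true group, cols: predicted
    per_group_reclassification: dict[str, float]
    overall_reclassification: float
    null_distribution: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    regularized: bool = False

    def summary(self) -> str:
        lines = ["Permuted discriminant function analysis",
                 f"  overall reclassification: "
                 f"{100 * self.overall_reclassification:.1f}%"]
        for g, r in sorted(self.per_group_reclassification.items()):
            lines.append(f"  {g}: {100 * r:.1f}%")
        lines.append(
            f"  p = {self.p_value:.4g} ({self.n_permutations} permutations, "
            f"null mean {100 * float(np.mean(self.null_distribution)):.1f}%)")
        return "\n".join(lines)


def pdfa(scores: Union[np.ndarray, pd.DataFrame],
         labels: Sequence[str],
         n_permutations: int = 1000,
         seed: int = 0) -> PDFAResult:
    """Permuted discriminant function analysis.

    The observed discrimination quality is the leave-one-out cross-validated
    linear-discriminant reclassification rate of events to groups; the null
    distribution repeats the procedure on label permutations, and
    ``p = (count(null >= observed) + 1) / (n_permutations + 1)``.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("scores and labels disagree in length")
    classes, yi = np.unique(y, return_inverse=True)
    k = classes.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    for c in range(k):
        if np.sum(yi == c) < 3:
            raise ValueError("each group needs at least 3 events")

    preds, regularized = _loo_lda_predict(X, yi, k)
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (yi, preds), 1)
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    per_group = {str(g): conf[i, i] / conf[i].sum()
                 for i, g in enumerate(classes)}
    overall = float(np.trace(conf)) / X.shape[0]

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(yi)
        pp, _ = _loo_lda_predict(X, yp, k)
        null[b] = float(np.mean(pp == yp))
    p = (float(np.sum(null >= overall - 1e-12)) + 1.0) / (n_permutations + 1.0)
    return PDFAResult(confusion=confusion,
                      per_group_reclassification=per_group,
                      overall_reclassification=overall,
                      null_distribution=null, p_value=p,
                      n_permutations=n_permutations, seed=seed,
                      regularized=regularized)


# ---------------------------------------------------------------------------
# geography-projected clustering


@dataclass
class GeoClustering:
    """Average-linkage tree over per-group acoustic medians, with the cave
    coordinates needed to project it onto a map."""

    linkage_matrix: np.ndarray
    labels: list[str]
    group_coordinates: dict[str, tuple[float, float]]
    newick: str
    medians: pd.DataFrame


def _to_newick(node, labels: list[str]) -> str:
    def rec(nd, parent_dist: float) -> str:
        length = parent_dist - nd.dist
        if nd.is_leaf():
            return f"{labels[nd.id]}:{length:.6g}"
        left = rec(nd.left, nd.dist)
        right = rec(nd.right, nd.dist)
        return f"({left},{right}):{length:.6g}"

    if node.is_leaf():
        return f"{labels[node.id]}:0;"
    left = rec(node.left, node.dist)
    right = rec(node.right, node.dist)
    return f"({left},{right});"


def geo_cluster(table: FeatureTable,
                coordinates: Mapping[str, tuple[float, float]]
                ) -> GeoClustering:
    """Hierarchical clustering of groups in acoustic space.

    Each group is summarized by the median of its per-column standardized
    feature vector; groups are merged by average linkage on Euclidean
    distances.  The tree serializes to Newick with merge heights as branch
    lengths; plotting places the leaves at the groups' (longitude,
    latitude).
    """
    groups = table.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    missing = [g for g in groups if g not in coordinates]
    if missing:
        raise KeyError(f"missing coordinates for groups {missing}")
    X = table.values()
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    zdf = pd.DataFrame(Z, columns=table.feature_names)
    zdf["group"] = table.df["group"].to_numpy()
    medians = zdf.groupby("group", observed=True).median().loc[groups]
    if len(groups) == 2:
        d = float(np.linalg.norm(medians.iloc[0] - medians.iloc[1]))
        lm = np.array([[0.0, 1.0, d, 2.0]])
    else:
        lm = linkage(pdist(medians.to_numpy(float)), method="average")
    tree = to_tree(lm)
    newick = _to_newick(tree, groups)
    return GeoClustering(linkage_matrix=lm, labels=list(groups),
                         group_coordinates={g: tuple(coordinates[g])
                                            for g in groups},
                         newick=newick, medians=medians)
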