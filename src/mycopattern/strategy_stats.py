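"""Statistical stages of the colonization-strategy analysis.

The analysis runs on the index table (one row of seven colonization indices
per observation, or per-segment means) and comprises:

- dual histograms per index: a best-fitted solution (automatic Sturges
  binning on the observed range) and a class-restricted solution forcing
  the five 20%-wide frequency-class bins;
- one-way ANOVA across frequency classes with Fisher's protected LSD
  post-hoc test and a compact letter display;
- pairwise ordinary-least-squares regressions between indices (the five
  canonical pairs: F->I, F->Arb, I->Arb, Cdeg->Arb, Cdeg->ratio);
- ordination: PCA on standardized indices and non-metric multidimensional
  scaling (NMDS) on Bray-Curtis dissimilarities;
- hierarchical (Ward) clustering of segment-level records cut into k
  strategy clusters, with a centroid table and per-cluster representative
  colonization maps.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SKPCA
from sklearn.manifold import MDS as _SKMDS

from .grid_model import ColonizationGrid, ColorMap, ObservationID, render_map
from .indices import (
    CLASS_LABELS,
    FREQUENCY_CLASSES,
    INDEX_COLUMNS,
    ColonizationRecord,
    records_to_frame,
)

logger = logging.getLogger(__name__)

#: the five canonical predictor->response regression pairs
REGRESSION_PAIRS = [
    ("frequency", "intensity"),
    ("frequency", "arbuscules"),
    ("intensity", "arbuscules"),
    ("colonization_degree", "arbuscules"),
    ("colonization_degree", "m_nonm_ratio"),
]

CLASS_BIN_EDGES = [0.0, 20.0, 40.0, 60.0, 80.0, 100.0]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def _check_parameter(df: pd.DataFrame, parameter: str) -> None:
    if parameter not in df.columns:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {INDEX_COLUMNS}")


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistogramResult:
    parameter: str
    solution: str  # "best_fitted" | "class_restricted"
    bin_edges: np.ndarray
    counts: np.ndarray


def histogram(records, parameter: str, solution: str = "best_fitted") -> HistogramResult:
    """Histogram of one index, either auto-binned or class-restricted.

    ``best_fitted`` uses Sturges' rule on the observed range; for ~900
    observations spanning 0-100% this yields the familiar ~10%-wide bins.
    ``class_restricted`` forces the five frequency-class bins
    [0,20], (20,40], ..., (80,100], closed on the right like the class
    assignment itself.
    """
    df = _as_frame(records)
    _check_parameter(df, parameter)
    values = df[parameter].to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("no records")
    if solution == "best_fitted":
        edges = np.histogram_bin_edges(values, bins="sturges")
        counts, edges = np.histogram(values, bins=edges)
    elif solution == "class_restricted":
        edges = np.asarray(CLASS_BIN_EDGES)
        # right-closed bins with 0 included in the first bin
        idx = np.clip(np.ceil(np.maximum(values, 1e-12) / 20.0).astype(int) - 1, 0, 4)
        counts = np.bincount(idx, minlength=5)
    else:
        raise ValueError(f"unknown solution {solution!r}")
    return HistogramResult(parameter, solution, np.asarray(edges, float), counts)


# ---------------------------------------------------------------------------
# ANOVA with protected LSD and compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    parameter: str
    f_statistic: float
    p_value: float
    alpha: float
    groups: list[str]          # ordered by descending mean
    means: dict[str, float]
    ses: dict[str, float]
    ns: dict[str, int]
    letters: dict[str, str]    # compact letter display per group


def _compact_letter_display(
    groups: Sequence[str], means: dict[str, float], distinct: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` are ordered by descending mean; ``distinct`` holds the pairs
    declared significantly different. Each letter column is a set of groups
    not separated from each other; a group's string is the letters of the
    columns containing it.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in distinct:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb columns that became subsets of others
        columns = [
            c for c in columns
            if c and not any(c < other for other in columns if other is not c)
        ]
        # deduplicate
        uniq: list[set[str]] = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    # order columns by the best (largest-mean) member so 'a' marks the top
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def anova_lsd(records, parameter: str, alpha: float = 0.05,
              group_col: str = "freq_class") -> AnovaResult:
    """One-way ANOVA across groups with Fisher's protected LSD letters.

    Groups with fewer than two records are excluded with a warning; at
    least two remaining groups are required. Pairwise LSD comparisons (t
    tests on the pooled within-group mean square, df = N - k) are performed
    only when the omnibus ANOVA rejects at ``alpha`` — the protection that
    keeps the family-wise error at the nominal level under the complete
    null. The letter display orders letters by descending group mean.
    """
    df = _as_frame(records)
    _check_parameter(df, parameter)
    grouped = {str(k): sub[parameter].to_numpy(float) for k, sub in df.groupby(group_col)}
    for k in [k for k, v in grouped.items() if len(v) < 2]:
        logger.warning("group %s has <2 records; excluded from ANOVA", k)
        del grouped[k]
    if len(grouped) < 2:
        raise ValueError("ANOVA requires at least two groups with >=2 records")

    names = list(grouped)
    samples = [grouped[k] for k in names]
    ns = {k: len(v) for k, v in grouped.items()}
    means = {k: float(v.mean()) for k, v in grouped.items()}
    ses = {k: float(v.std(ddof=1) / math.sqrt(len(v))) for k, v in grouped.items()}
    n_total = sum(ns.values())
    k_groups = len(names)
    grand = sum(v.sum() for v in samples) / n_total
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in samples)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in samples)
    df_b, df_w = k_groups - 1, n_total - k_groups
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        f_stat = 0.0 if ss_between == 0.0 else math.inf
        p_value = 1.0 if ss_between == 0.0 else 0.0
    else:
        f_stat = (ss_between / df_b) / ms_within
        p_value = float(st.f.sf(f_stat, df_b, df_w))

    order = sorted(names, key=lambda g: -means[g])
    distinct: set[tuple[str, str]] = set()
    if p_value < alpha and ms_within > 0.0:
        for a, b in itertools.combinations(order, 2):
            se_diff = math.sqrt(ms_within * (1.0 / ns[a] + 1.0 / ns[b]))
            t = abs(means[a] - means[b]) / se_diff
            if 2.0 * st.t.sf(t, df_w) < alpha:
                distinct.add((a, b))
    letters = _compact_letter_display(order, means, distinct)
    return AnovaResult(parameter, float(f_stat), p_value, alpha,
                       order, means, ses, ns, letters)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    predictor: str
    response: str
    intercept: float
    slope: float
    resid_std: float
    r_squared: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_regression(records, predictor: str, response: str) -> RegressionResult:
    """Ordinary least-squares line response ~ predictor."""
    df = _as_frame(records)
    _check_parameter(df, predictor)
    _check_parameter(df, response)
    x = df[predictor].to_numpy(float)
    y = df[response].to_numpy(float)
    if len(x) < 3:
        raise ValueError("regression requires at least 3 records")
    if np.ptp(x) == 0.0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid_std = float(np.sqrt(model.ssr / model.df_resid)) if model.df_resid > 0 else 0.0
    return RegressionResult(
        predictor=predictor,
        response=response,
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        resid_std=resid_std,
        r_squared=float(model.rsquared),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    method: str                 # "PCA" | "NMDS"
    scores: np.ndarray          # n x 2 sample configuration
    loadings: pd.DataFrame      # variables x 2 (PCA loadings / NMDS vectors)
    variance_pct: np.ndarray | None = None   # PCA: % variance, all axes
    stress: float | None = None              # NMDS: Kruskal stress-1
    distance: str | None = None


def pca(records, variables: Sequence[str] | None = None) -> OrdinationResult:
    """PCA of the (centered, unit-variance) colonization indices.

    Constant variables are dropped with a warning. Scores are returned for
    the first two axes; the explained-variance percentages cover all axes
    (they sum to 100).
    """
    df = _as_frame(records)
    variables = list(variables or INDEX_COLUMNS)
    for v in variables:
        _check_parameter(df, v)
    X = df[variables].to_numpy(float)
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 records")
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    dropped = [variables[i] for i in range(X.shape[1]) if i not in keep]
    if dropped:
        logger.warning("constant variables dropped from PCA: %s", dropped)
    if not keep:
        raise ValueError("all variables constant; PCA is degenerate")
    variables = [variables[i] for i in keep]
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    model = _SKPCA()
    scores = model.fit_transform(Z)
    # sign convention: orient each axis so its largest-|loading| is positive
    comps = model.components_
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            scores[:, i] *= -1.0
    loadings = pd.DataFrame(comps[:2].T, index=variables, columns=["axis1", "axis2"])
    return OrdinationResult(
        method="PCA",
        scores=scores[:, :2],
        loadings=loadings,
        variance_pct=model.explained_variance_ratio_ * 100.0,
    )


def nmds(records, variables: Sequence[str] | None = None,
         distance: str = "braycurtis", seed: int = 42,
         n_restarts: int = 20) -> OrdinationResult:
    """Two-dimensional non-metric multidimensional scaling.

    Dissimilarities default to Bray-Curtis on the raw (non-negative) index
    values; the SMACOF configuration with the lowest Kruskal stress-1 over
    ``n_restarts`` seeded restarts is returned. Variable vectors are the
    Pearson correlations of each index with the two axes (envfit-style).
    """
    df = _as_frame(records)
    variables = list(variables or INDEX_COLUMNS)
    for v in variables:
        _check_parameter(df, v)
    X = df[variables].to_numpy(float)
    if X.shape[0] < 4:
        raise ValueError("NMDS requires at least 4 records")
    if np.ptp(X, axis=0).max() == 0.0:
        raise ValueError("all records identical; NMDS is degenerate")
    if distance == "braycurtis" and X.min() < 0:
        raise ValueError("Bray-Curtis requires non-negative data")
    d = pdist(X, metric=distance)
    if np.isnan(d).any():
        # Bray-Curtis between two all-zero rows is 0/0; such pairs are identical
        logger.warning("undefined dissimilarities (all-zero pairs) set to 0")
        d = np.nan_to_num(d, nan=0.0)
    model = _SKMDS(
        n_components=2,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=300,
    )
    scores = model.fit_transform(squareform(d))
    vecs = {}
    for i, v in enumerate(variables):
        col = X[:, i]
        if np.ptp(col) == 0:
            vecs[v] = (0.0, 0.0)
        else:
            vecs[v] = (
                float(np.corrcoef(col, scores[:, 0])[0, 1]),
                float(np.corrcoef(col, scores[:, 1])[0, 1]),
            )
    loadings = pd.DataFrame.from_dict(vecs, orient="index", columns=["axis1", "axis2"])
    return OrdinationResult(
        method="NMDS",
        scores=scores,
        loadings=loadings,
        stress=float(model.stress_),
        distance=distance,
    )


# ---------------------------------------------------------------------------
# Strategy clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyCluster:
    cluster_id: str                       # "C1".."Ck", in order of first member
    member_ids: tuple
    centroid: dict[str, float]            # member means of each index, raw scale
    share_pct: float


def cluster_strategies(segment_records, k: int = 9, linkage: str = "ward",
                       distance: str = "euclidean") -> list[StrategyCluster]:
    """Cut an agglomerative dendrogram of (segment-level) records into k
    strategy clusters.

    Records are standardized per index (z-scores) before Ward/Euclidean
    linkage so that the percentage indices and the M/nonM ratio weigh
    equally. Clusters are relabeled C1..Ck in input order of their first
    member; centroids are member means on the raw index scale and shares
    are percentages of the record count.
    """
    df = _as_frame(segment_records).reset_index(drop=True)
    n = len(df)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of records n={n}")
    X = df[INDEX_COLUMNS].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0.0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    if k == n:
        labels = np.arange(n)
    elif k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        link = sch.linkage(Z, method=linkage, metric=distance)
        labels = sch.fcluster(link, t=k, criterion="maxclust")
    # relabel by first appearance
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    id_cols = [c for c in ("replication", "segment", "field") if c in df.columns]
    clusters = []
    for lab, idx in sorted(((lab, i) for lab, i in order.items()), key=lambda t: t[1]):
        mask = labels == lab
        members = df.loc[mask]
        if id_cols:
            member_ids = tuple(map(tuple, members[id_cols].to_numpy()))
        else:
            member_ids = tuple(members.index)
        centroid = {c: float(members[c].mean()) for c in INDEX_COLUMNS}
        clusters.append(
            StrategyCluster(
                cluster_id=f"C{idx + 1}",
                member_ids=member_ids,
                centroid=centroid,
                share_pct=100.0 * mask.sum() / n,
            )
        )
    return clusters


def centroid_table(clusters: Sequence[StrategyCluster]) -> pd.DataFrame:
    """Cluster centroid table (one row per cluster, plus share of data)."""
    rows = {c.cluster_id: {**c.centroid, "share_pct": c.share_pct, "n": len(c.member_ids)}
            for c in clusters}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cluster"
    return out


# ---------------------------------------------------------------------------
# Strategy report: representative maps per cluster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyReport:
    clusters: list[StrategyCluster]
    centroids: pd.DataFrame
    representatives: dict[str, ObservationID | None]
    maps: dict[str, ColorMap | None]


def strategy_report(clusters: Sequence[StrategyCluster],
                    grids: Sequence[ColonizationGrid]) -> StrategyReport:
    """One representative colonization map per cluster.

    The representative is the member observation whose indices lie nearest
    the cluster centroid in standardized index space (z-scores over all
    grids). Cluster membership is matched on the leading components of the
    member ids (e.g. segment-level clusters match all fields of their
    member segments). A cluster with no grid data gets a None placeholder.
    """
    from .indices import compute_indices  # local import to avoid cycle at module load

    if not grids:
        logger.warning("no grid data; placeholder report emitted")
        return StrategyReport(
            clusters=list(clusters),
            centroids=centroid_table(clusters),
            representatives={c.cluster_id: None for c in clusters},
            maps={c.cluster_id: None for c in clusters},
        )
    df = records_to_frame([compute_indices(g) for g in grids])
    by_id = {g.id: g for g in grids}
    X = df[INDEX_COLUMNS].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0.0] = 1.0
    mu = X.mean(axis=0)

    representatives: dict[str, ObservationID | None] = {}
    maps: dict[str, ColorMap | None] = {}
    for cluster in clusters:
        prefixes = {tuple(m)[:2] if len(tuple(m)) >= 2 else tuple(m)
                    for m in cluster.member_ids}
        width = len(next(iter(prefixes))) if prefixes else 0
        mask = df.apply(
            lambda row: (int(row["replication"]), int(row["segment"]))[:width] in prefixes,
            axis=1,
        ).to_numpy()
        if not mask.any():
            logger.warning("cluster %s has no grid data; placeholder emitted",
                           cluster.cluster_id)
            representatives[cluster.cluster_id] = None
            maps[cluster.cluster_id] = None
            continue
        centroid_z = (np.array([cluster.centroid[c] for c in INDEX_COLUMNS]) - mu) / sd
        Z = (X[mask] - mu) / sd
        best = int(np.argmin(((Z - centroid_z) ** 2).sum(axis=1)))
        row = df.loc[mask].iloc[best]
        oid = ObservationID(int(row["replication"]), int(row["segment"]), int(row["field"]))
        representatives[cluster.cluster_id] = oid
        maps[cluster.cluster_id] = render_map(by_id[oid])
    return StrategyReport(
        clusters=list(clusters),
        centroids=centroid_table(clusters),
        representatives=representatives,
        maps=maps,
    )
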