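"""Cohort-level statistics: volcano-style group comparison and KNN-density
(X-shift-style) patient clustering.

Group comparison uses Welch's two-sided t-test per feature with
Benjamini-Hochberg adjustment across the feature family; samples excluded by
the zero-denominator rule are dropped per feature.  Patient clustering
re-implements the X-shift idea in simplified form: each patient's local
density is the inverse mean distance to its K nearest neighbours, every
patient links to its nearest strictly-denser neighbour within that
neighbourhood, link-free patients are modes, and clusters are the ascent
trees rooted at the modes (no Mahalanobis weighting and no mode merging by
gap test — an approximation of the published algorithm).  K defaults to 20
and can be selected from the elbow of the cluster-count-vs-K curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

__all__ = [
    "compare_groups",
    "XShiftCluster",
    "PatientClustering",
    "knn_density_cluster",
    "elbow_select_K",
    "flag_msi_like",
]


def compare_groups(
    features: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    group_a: str,
    group_b: str,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-feature Welch t-test between two sample groups, volcano-style.

    ``features`` is samples × features (NaN = excluded sample for that
    feature); ``groups`` labels each sample.  Returns one row per feature with
    group means ± SEM, log2 fold-change of group means (A over B; finite only
    when both means are positive), the two-sided Welch p value and the
    multiplicity-adjusted p value (Benjamini-Hochberg by default,
    ``adjust="bonferroni"`` selectable).  Features with fewer than two
    evaluable samples in either group are flagged not evaluable.
    """
    groups = pd.Series(np.asarray(groups), index=features.index)
    present = set(groups.unique())
    if group_a not in present or group_b not in present:
        raise ConfigurationError(
            f"groups {group_a!r} and {group_b!r} must both be present, found {sorted(map(str, present))}"
        )
    rows = []
    for feat in features.columns:
        xa = features.loc[groups == group_a, feat].dropna().to_numpy(dtype=float)
        xb = features.loc[groups == group_b, feat].dropna().to_numpy(dtype=float)
        evaluable = len(xa) >= 2 and len(xb) >= 2
        row = {
            "feature": feat,
            "n_a": len(xa), "n_b": len(xb),
            "mean_a": xa.mean() if len(xa) else np.nan,
            "mean_b": xb.mean() if len(xb) else np.nan,
            "sem_a": stats.sem(xa) if len(xa) >= 2 else np.nan,
            "sem_b": stats.sem(xb) if len(xb) >= 2 else np.nan,
            "evaluable": evaluable,
        }
        if evaluable:
            ma, mb = row["mean_a"], row["mean_b"]
            row["log2_fc"] = np.log2(ma / mb) if ma > 0 and mb > 0 else np.nan
            if np.ptp(xa) == 0 and np.ptp(xb) == 0:
                # both groups constant: identical -> no evidence, else infinite t
                row["t_stat"] = np.nan
                row["p_value"] = 1.0 if ma == mb else 0.0
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
                row["t_stat"], row["p_value"] = float(t), float(p)
        else:
            row["log2_fc"] = np.nan
            row["t_stat"] = np.nan
            row["p_value"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adjusted"] = np.nan
    mask = out["evaluable"] & out["p_value"].notna()
    if mask.any():
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "p_value"].to_numpy(), method=adjust,
        )[1]
    return out


class XShiftCluster(ClusterMixin, BaseEstimator):
    """KNN-density ascent clustering (simplified X-shift).

    Parameters
    ----------
    n_neighbors : int, default 20
        K of the density estimate and the linking neighbourhood.
    standardize : bool, default True
        z-score each feature before distances are computed (composition
        fractions and interaction values live on different scales).

    Attributes (after ``fit``)
    --------------------------
    labels_ : cluster id per sample, contiguous from 0, ordered by mode index.
    density_ : inverse mean distance to the K nearest neighbours.
    modes_ : sample indices of the density modes (one per cluster).
    cluster_centers_ : per-cluster feature means on the original scale.
    n_clusters_ : number of clusters.

    Ties in density (e.g. exact duplicate points) are broken toward the
    smaller sample index, which makes the ascent acyclic and the result
    independent of point order after sorting.
    """

    def __init__(self, n_neighbors: int = 20, standardize: bool = True):
        self.n_neighbors = n_neighbors
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.isfinite(X).all():
            raise ValueError("X must be finite")
        n, k = len(X), int(self.n_neighbors)
        if k < 1:
            raise ValueError(f"n_neighbors must be >= 1, got {k}")
        if k >= n:
            raise ValueError(f"n_neighbors={k} must be < n_samples={n}")
        Z = X
        if self.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            Z = (X - mu) / np.where(sd > 0, sd, 1.0)

        nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
        dist, idx = nn.kneighbors(Z)
        # drop self from each neighbour list (with exact duplicates, self may
        # not be in column 0, or may be missing entirely)
        own = np.arange(n)
        nbrs = np.empty((n, k), dtype=np.int64)
        nbd = np.empty((n, k))
        for i in range(n):
            row = idx[i]
            pos = np.flatnonzero(row == i)
            j = pos[0] if len(pos) else k
            keep = np.concatenate([np.arange(j), np.arange(j + 1, k + 1)])[:k]
            nbrs[i] = row[keep]
            nbd[i] = dist[i, keep]
        mean_d = nbd.mean(axis=1)
        with np.errstate(divide="ignore"):
            density = np.where(mean_d > 0, 1.0 / mean_d, np.inf)

        dj = density[nbrs]
        di = density[:, None]
        better = (dj > di) | ((dj == di) & (nbrs < own[:, None]))
        # link to the NEAREST denser neighbour (neighbour lists are
        # distance-ordered); points with no denser neighbour are modes
        first = better.argmax(axis=1)
        has_denser = better.any(axis=1)
        parent = np.where(has_denser, nbrs[own, first], own)

        # pointer jumping to the root of each ascent tree
        root = parent.copy()
        while True:
            nxt = root[root]
            if np.array_equal(nxt, root):
                break
            root = nxt
        modes = np.unique(root)
        labels = np.searchsorted(modes, root)

        self.labels_ = labels
        self.density_ = density
        self.modes_ = modes
        self.n_clusters_ = len(modes)
        self.cluster_centers_ = np.vstack(
            [X[labels == c].mean(axis=0) for c in range(len(modes))]
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class PatientClustering:
    """Patient clustering result: one cluster id per patient, plus the
    per-cluster mean composition on the original feature scale."""

    labels: pd.Series
    n_neighbors: int
    n_clusters: int
    cluster_means: pd.DataFrame


def knn_density_cluster(matrix: pd.DataFrame, K: int = 20) -> PatientClustering:
    """Cluster patients by their composition profiles (X-shift style).

    ``matrix`` is patients × features; requires n patients > K.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(X))
    columns = matrix.columns if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    try:
        est = XShiftCluster(n_neighbors=K).fit(X)
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
    labels = pd.Series(est.labels_, index=index, name="cluster")
    means = pd.DataFrame(est.cluster_centers_, columns=columns)
    means.index.name = "cluster"
    return PatientClustering(labels, K, est.n_clusters_, means)


def elbow_select_K(matrix: pd.DataFrame, K_grid) -> int:
    """Choose K at the elbow of the cluster-count-vs-K curve.

    Runs the clustering for every K of the ascending grid, records the
    cluster count, and returns the K with the maximum discrete second
    difference (point of maximum curvature); ties resolve to the smaller K.
    A completely flat curve returns the smallest K with a warning.
    """
    grid = [int(k) for k in K_grid]
    if len(grid) < 3:
        raise ConfigurationError("K grid needs at least 3 values")
    if sorted(grid) != grid or len(set(grid)) != len(grid):
        raise ConfigurationError("K grid must be strictly ascending")
    counts = np.array([knn_density_cluster(matrix, K=k).n_clusters for k in grid], float)
    return elbow_from_counts(counts, grid)


def elbow_from_counts(counts, K_grid) -> int:
    """The elbow rule itself: K at the maximum discrete second difference of
    the cluster-count curve (ties → smaller K; flat curve → smallest K)."""
    counts = np.asarray(counts, dtype=float)
    grid = list(K_grid)
    if np.ptp(counts) == 0:
        warnings.warn("cluster-count curve is flat: returning the smallest K", stacklevel=2)
        return grid[0]
    d2 = counts[:-2] - 2.0 * counts[1:-1] + counts[2:]
    return grid[1 + int(np.argmax(d2))]


def flag_msi_like(
    clustering: PatientClustering,
    profiles: pd.DataFrame,
    reference: pd.Series,
) -> pd.Series:
    """Flag the patients of the cluster nearest to an MSI reference profile.

    The distance is Euclidean over the reference's features (subpopulation
    fractions); the nearest cluster's members are flagged True.  Ties and the
    single-cluster case resolve to the smaller cluster id / all patients
    (with a warning).
    """
    missing = [c for c in reference.index if c not in profiles.columns]
    if missing:
        raise ConfigurationError(f"profiles lack reference features: {missing}")
    if not profiles.index.equals(clustering.labels.index):
        raise ConfigurationError("profiles and clustering cover different patients")
    if clustering.n_clusters == 1:
        warnings.warn("single cluster: flagging all patients", stacklevel=2)
        return pd.Series(True, index=profiles.index, name="msi_like")
    feats = list(reference.index)
    ref = reference.to_numpy(dtype=float)
    dists = []
    for c in range(clustering.n_clusters):
        members = profiles.loc[clustering.labels == c, feats]
        centre = members.mean(axis=0).to_numpy(dtype=float)
        dists.append(np.linalg.norm(centre - ref))
    nearest = int(np.argmin(dists))  # argmin takes the smaller cluster id on ties
    return pd.Series(clustering.labels == nearest, name="msi_like")
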