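"""Time-course hierarchical clustering with Krzanowski-Lai model selection.

Profiles (feature x time M-values) are clustered by Ward's
variance-minimizing linkage on Euclidean input.  The number of clusters is
chosen by the Krzanowski-Lai index: with W_k the total within-cluster sum
of squared distances to centroids at k clusters and p the profile
dimension,

    DIFF(k) = (k-1)^{2/p} W_{k-1} - k^{2/p} W_k
    KL(k)   = |DIFF(k)| / |DIFF(k+1)|

and the maximizer of KL(k) over k in [2, k_max] estimates the cluster
count.  :class:`KLWardClustering` packages the whole procedure as a
scikit-learn compatible estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .dynamics import benjamini_hochberg


@dataclass
class ClusterSolution:
    assignments: pd.Series          # feature -> cluster id (1..k)
    k: int
    merge_heights: np.ndarray
    W: np.ndarray | None = None     # W_k for k = 1..k_max+1 (index 0 <-> k=1)
    KL: np.ndarray | None = None    # KL(k) for k = 2..k_max (NaN where undefined)
    k_opt: int | None = None
    flat_structure: bool = False
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# profile preparation
# ---------------------------------------------------------------------------

def prepare_profiles(m_table: pd.DataFrame, n_timepoints: int | None = None) -> pd.DataFrame:
    """Availability filter and neighbor imputation.

    Features need observed M-values at >= ceil(2/3 n_t) time points (7 time
    points -> at least 5); a single missing interior time point is replaced
    by the mean of the two neighboring time points (linear interpolation,
    which coincides with the neighbor mean for single gaps); a missing
    first/last time point copies the nearest observed value.
    """
    wide = m_table.pivot_table(index="feature", columns="time", values="M", dropna=False)
    n_t = n_timepoints or wide.shape[1]
    need = int(np.ceil(2.0 * n_t / 3.0))
    wide = wide[wide.notna().sum(axis=1) >= need]
    filled = wide.interpolate(axis=1, method="linear", limit_direction="both")
    return filled


# ---------------------------------------------------------------------------
# Ward + KL primitives
# ---------------------------------------------------------------------------

def ward_linkage(X: np.ndarray) -> np.ndarray:
    """Ward's linkage on Euclidean input (Lance-Williams variance-minimizing
    update)."""
    return linkage(X, method="ward")


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    return fcluster(Z, t=k, criterion="maxclust")


def ward_cluster(profiles: pd.DataFrame | np.ndarray, k: int) -> ClusterSolution:
    X = np.asarray(profiles, dtype=float)
    if np.isnan(X).any():
        raise ValueError("profiles contain missing values; run prepare_profiles first")
    if k > len(X):
        raise ValueError(f"k={k} exceeds n={len(X)} features")
    Z = ward_linkage(X)
    labels = cut_tree(Z, k)
    index = profiles.index if isinstance(profiles, pd.DataFrame) else pd.RangeIndex(len(X))
    return ClusterSolution(pd.Series(labels, index=index), int(labels.max()), Z[:, 2])


def within_dispersion(profiles: np.ndarray | pd.DataFrame, assignments: np.ndarray | pd.Series
                      ) -> float:
    """W = sum over clusters of squared Euclidean distances to the cluster
    centroid."""
    X = np.asarray(profiles, dtype=float)
    labels = np.asarray(assignments)
    if len(labels) != len(X) or len(labels) == 0:
        raise ValueError("assignments must label every profile (and at least one)")
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        if len(members) == 0:
            raise ValueError(f"empty cluster {lab}")
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


def kl_optimal_k(W: np.ndarray, p: int, k_max: int = 50) -> tuple[np.ndarray, int]:
    """Krzanowski-Lai trace and its maximizer.

    ``W`` holds W_k for k = 1..k_max+1 (so DIFF(k+1) exists up to k_max).
    Returns (KL values for k = 2..k_max, k_opt); ties and zero DIFF(k+1)
    entries resolve toward the smallest k.  A flat W trace (all DIFF zero)
    raises no error but yields KL of NaN everywhere and k_opt 2 with a
    warning.
    """
    W = np.asarray(W, dtype=float)
    if p < 1:
        raise ValueError("profile dimension p must be >= 1")
    if len(W) < k_max + 1:
        k_max = len(W) - 1
    if k_max < 2:
        raise ValueError("need W defined for at least k = 1..3")
    ks = np.arange(1, k_max + 2)
    wk = ks ** (2.0 / p) * W[:k_max + 1]
    diff = wk[:-1] - wk[1:]                     # DIFF(k) for k = 2..k_max+1
    with np.errstate(divide="ignore", invalid="ignore"):
        kl = np.abs(diff[:-1]) / np.abs(diff[1:])   # KL(k) for k = 2..k_max
    finite = np.isfinite(kl)
    if not finite.any():
        warnings.warn("all DIFF values vanish or are undefined; flat structure")
        return kl, 2
    k_opt = int(np.nanargmax(np.where(finite, kl, -np.inf)) + 2)
    vals = kl[finite]
    if len(vals) > 1 and np.nanmax(vals) <= 1.1 * np.nanmedian(vals):
        warnings.warn("low KL contrast: the index trace is nearly flat, "
                      "k_opt is weakly determined")
    return kl, k_opt


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class KLWardClustering(ClusterMixin, BaseEstimator):
    """Ward hierarchical clustering with KL-selected cluster count.

    Parameters
    ----------
    k_max : int
        Largest cluster count considered (the search range is [2, k_max]).
    k : int or None
        Fixed cluster count; when given, model selection is skipped.

    Attributes (after ``fit``)
    --------------------------
    labels_ : ndarray, cluster id per sample at ``k_opt_``.
    k_opt_ : int, KL-selected (or fixed) cluster count.
    W_ : ndarray, within-dispersion trace for k = 1..k_max+1.
    KL_ : ndarray, KL index for k = 2..k_max.
    linkage_ : ndarray, scipy linkage matrix.
    """

    def __init__(self, k_max: int = 50, k: int | None = None):
        self.k_max = k_max
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (features x time points)")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; run prepare_profiles first")
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 samples to cluster")
        Z = ward_linkage(X)
        self.linkage_ = Z
        k_hi = min(self.k_max, n - 1)
        self.W_ = np.array([within_dispersion(X, cut_tree(Z, k))
                            for k in range(1, min(k_hi + 1, n) + 1)])
        if self.k is not None:
            self.k_opt_ = int(self.k)
            self.KL_ = None
        else:
            self.KL_, self.k_opt_ = kl_optimal_k(self.W_, p, k_max=k_hi)
        self.labels_ = cut_tree(Z, self.k_opt_)
        return self

    def solution(self, index: pd.Index | None = None) -> ClusterSolution:
        idx = index if index is not None else pd.RangeIndex(len(self.labels_))
        return ClusterSolution(pd.Series(self.labels_, index=idx), int(self.labels_.max()),
                               self.linkage_[:, 2], self.W_, self.KL_, self.k_opt_)


def cluster_profiles_klward(profiles: pd.DataFrame, k_max: int = 50,
                            k: int | None = None) -> ClusterSolution:
    """Cluster a prepared profile matrix and return the full solution."""
    est = KLWardClustering(k_max=k_max, k=k).fit(profiles.to_numpy(dtype=float))
    return est.solution(profiles.index)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def cluster_profiles(solution: ClusterSolution, profiles: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cluster arithmetic-mean profile and cluster sizes."""
    grouped = profiles.groupby(solution.assignments)
    return grouped.mean(), grouped.size().rename("size")


def category_enrichment(solution: ClusterSolution, labels: pd.Series,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric tail test per (cluster, category) with BH adjustment.

    For a cluster of size n containing x members of a category with K
    members in the population of size N, p = P[X >= x], X ~
    Hypergeometric(N, K, n).
    """
    labels = labels.reindex(solution.assignments.index)
    N = len(labels)
    rows = []
    for cluster, members in solution.assignments.groupby(solution.assignments):
        in_cluster = labels.loc[members.index]
        n = len(in_cluster)
        for cat, K in labels.value_counts().items():
            x = int((in_cluster == cat).sum())
            p = float(stats.hypergeom.sf(x - 1, N, int(K), n))
            rows.append({"cluster": cluster, "category": cat, "cluster_size": n,
                         "category_size": int(K), "hits": x, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
    table["enriched"] = table["p_adj"] < alpha
    return table
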