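"""Growing central-vector clustering with a radius significance criterion.

Frequency vectors of genetically similar populations condense around common
centers; each center can be read as a hypothetical ancestral profile.  The
clusterer below searches for those condensation centers with a
vector-quantization refinement (nearest-center assignment followed by
centroid updates, restart-stabilized), and *grows* the number of centers N
starting from ``n_start`` until every multi-member cluster is tight relative
to its surroundings:

    radius(i) < ratio * delta(i)

where ``radius(i)`` is the mean Euclidean distance of cluster *i*'s members
from their center, ``delta(i)`` the distance from center *i* to the nearest
other center, and ``ratio`` defaults to 1/3.  Growth proceeds by splitting
the worst-violating cluster at its farthest member; each N is additionally
re-initialized from random data points ``n_restarts`` times and the solution
with the lowest total within-cluster distance is kept.  Singleton clusters
satisfy the criterion trivially.

Diagnostics mirror the downstream analysis: per-cluster radii, a paired
t-test that members are closer to their own center than to the nearest other
center, the binary same-cluster ("inherence") matrix, and its correlation
with a population distance matrix (well-separated clusters give a strongly
*negative* correlation, since same-cluster pairs are the close ones).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .freqmatrix import FrequencyMatrix

__all__ = [
    "SelfOrganizingCloud",
    "fit_soc",
    "cluster_radius",
    "significance_check",
    "inherence_matrix",
    "inherence_distance_correlation",
]


def _as_array(data) -> tuple[np.ndarray, Optional[list]]:
    if isinstance(data, FrequencyMatrix):
        df = data.usable_values()
        return df.to_numpy(dtype=float), list(df.index)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index)
    return np.asarray(data, dtype=float), None


def _refine(
    X: np.ndarray,
    centers: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Nearest-assignment / centroid-update refinement to a movement
    tolerance; empty clusters are re-seeded at the globally farthest point
    from its assigned center."""
    centers = centers.copy()
    n, _ = X.shape
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = cdist(X, centers)
        labels = dist.argmin(axis=1)
        # re-seed empty clusters at the point farthest from its own center
        for i in range(len(centers)):
            if not np.any(labels == i):
                own = dist[np.arange(n), labels]
                far = int(own.argmax())
                centers[i] = X[far]
                labels[far] = i
                dist = cdist(X, centers)
                labels = dist.argmin(axis=1)
        new_centers = np.stack(
            [X[labels == i].mean(axis=0) for i in range(len(centers))]
        )
        movement = float(np.linalg.norm(new_centers - centers, axis=1).max())
        centers = new_centers
        if movement < tol:
            break
    dist = cdist(X, centers)
    labels = dist.argmin(axis=1)
    inertia = float(dist[np.arange(n), labels].sum())
    return centers, labels, inertia


def _radii_and_deltas(
    X: np.ndarray, centers: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster mean member distance, nearest-other-center distance and
    member counts."""
    k = len(centers)
    radii = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    for i in range(k):
        members = X[labels == i]
        counts[i] = len(members)
        if len(members):
            radii[i] = float(
                np.linalg.norm(members - centers[i], axis=1).mean()
            )
    cc = cdist(centers, centers)
    np.fill_diagonal(cc, np.inf)
    deltas = cc.min(axis=1)
    return radii, deltas, counts


def _criterion_ok(
    radii: np.ndarray, deltas: np.ndarray, counts: np.ndarray, ratio: float
) -> bool:
    multi = counts >= 2
    return bool(np.all(radii[multi] < ratio * deltas[multi]))


class SelfOrganizingCloud(ClusterMixin, BaseEstimator):
    """Clusterer that grows its number of centers until every cluster's
    radius is below ``ratio`` times the distance to the nearest other center.

    Parameters
    ----------
    ratio : float, default=1/3
        Tightness criterion: mean member distance must be below ``ratio``
        times the nearest-other-center distance for every multi-member
        cluster.
    n_start : int, default=2
        Number of centers tried first.
    max_n : int or None
        Largest number of centers to try; ``None`` means up to the number of
        samples.  If reached without satisfying the criterion, the best
        solution is returned with ``converged_ = False``.
    n_restarts : int, default=10
        Random re-initializations per candidate N (best-of by total
        within-cluster distance), in addition to the split-based warm start.
    tol : float, default=1e-9
        Center-movement tolerance of the refinement loop.
    max_iter : int, default=300
        Refinement iterations per initialization.
    random_state : int or None
        Seed; identical seed and data give identical output.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (N, D)
    labels_ : ndarray of shape (n_samples,)
    n_clusters_ : int
    converged_ : bool
    inertia_ : float
        Total member-to-center distance.
    population_ids_ : list or None
        Row identifiers when fit from a FrequencyMatrix or DataFrame.
    """

    def __init__(
        self,
        ratio: float = 1.0 / 3.0,
        n_start: int = 2,
        max_n: Optional[int] = None,
        n_restarts: int = 10,
        tol: float = 1e-9,
        max_iter: int = 300,
        random_state: Optional[int] = None,
    ):
        self.ratio = ratio
        self.n_start = n_start
        self.max_n = max_n
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X_arr, ids = _as_array(X)
        if X_arr.ndim != 2 or not np.all(np.isfinite(X_arr)):
            raise ValueError("X must be a finite 2-D array")
        n = X_arr.shape[0]
        max_n = n if self.max_n is None else min(self.max_n, n)
        if max_n < self.n_start:
            raise ValueError(
                f"max_n={max_n} is smaller than n_start={self.n_start}"
            )
        if n < self.n_start:
            raise ValueError("fewer samples than n_start")
        rng = np.random.default_rng(self.random_state)

        best = None  # (centers, labels, inertia) for current N
        prev_best = None
        converged = False
        for k in range(self.n_start, max_n + 1):
            candidates = []
            if prev_best is not None:
                # warm start: split the worst-criterion cluster of the
                # previous solution at its farthest member
                centers, labels, _ = prev_best
                radii, deltas, counts = _radii_and_deltas(
                    X_arr, centers, labels
                )
                score = np.where(counts >= 2, radii / deltas, -np.inf)
                worst = int(score.argmax())
                members = np.flatnonzero(labels == worst)
                far = members[
                    int(
                        np.linalg.norm(
                            X_arr[members] - centers[worst], axis=1
                        ).argmax()
                    )
                ]
                candidates.append(np.vstack([centers, X_arr[far]]))
            for _ in range(self.n_restarts):
                idx = rng.choice(n, size=k, replace=False)
                candidates.append(X_arr[idx].copy())
            best = None
            for init in candidates:
                centers, labels, inertia = _refine(
                    X_arr, init, self.tol, self.max_iter
                )
                if best is None or inertia < best[2]:
                    best = (centers, labels, inertia)
            radii, deltas, counts = _radii_and_deltas(X_arr, best[0], best[1])
            if _criterion_ok(radii, deltas, counts, self.ratio):
                converged = True
                break
            prev_best = best

        self.cluster_centers_ = best[0]
        self.labels_ = best[1]
        self.inertia_ = best[2]
        self.n_clusters_ = len(best[0])
        self.converged_ = converged
        self.population_ids_ = ids
        self.n_features_in_ = X_arr.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X_arr, _ = _as_array(X)
        return cdist(X_arr, self.cluster_centers_).argmin(axis=1)


def fit_soc(
    data,
    ratio: float = 1.0 / 3.0,
    n_start: int = 2,
    max_n: Optional[int] = None,
    n_restarts: int = 10,
    seed: Optional[int] = None,
) -> SelfOrganizingCloud:
    """Fit a :class:`SelfOrganizingCloud` on a frequency matrix or array."""
    return SelfOrganizingCloud(
        ratio=ratio,
        n_start=n_start,
        max_n=max_n,
        n_restarts=n_restarts,
        random_state=seed,
    ).fit(data)


def cluster_radius(data, cvset: SelfOrganizingCloud, i: int) -> float:
    """Mean Euclidean distance of cluster ``i``'s members from its center
    (0 for a singleton)."""
    check_is_fitted(cvset, "cluster_centers_")
    X, _ = _as_array(data)
    members = X[cvset.labels_ == i]
    if len(members) == 0:
        raise ValueError(f"cluster {i} is empty")
    return float(np.linalg.norm(members - cvset.cluster_centers_[i], axis=1).mean())


def significance_check(data, cvset: SelfOrganizingCloud) -> pd.Series:
    """Per-cluster probability that members are closer to their own center
    than to the nearest other center.

    For each cluster with >= 3 members, a one-sided paired t-test compares
    member distances to the own center against distances to the nearest
    other center; the returned value is 1 - p.  Clusters with fewer than 3
    members, or with zero-variance differences, are marked not-computable
    (NaN).
    """
    check_is_fitted(cvset, "cluster_centers_")
    X, _ = _as_array(data)
    centers = cvset.cluster_centers_
    out = {}
    for i in range(cvset.n_clusters_):
        members = X[cvset.labels_ == i]
        if len(members) < 3:
            out[i] = np.nan
            continue
        d_all = cdist(members, centers)
        own = d_all[:, i]
        other = np.delete(d_all, i, axis=1).min(axis=1)
        diff = own - other
        if np.allclose(diff.std(ddof=1), 0.0):
            out[i] = np.nan
            continue
        with np.errstate(invalid="ignore"):
            res = stats.ttest_rel(own, other, alternative="less")
        out[i] = float(1.0 - res.pvalue) if np.isfinite(res.pvalue) else np.nan
    return pd.Series(out, name="significance")


def inherence_matrix(cvset_or_labels) -> np.ndarray:
    """Binary same-cluster indicator matrix (symmetric, ones on the
    diagonal)."""
    if isinstance(cvset_or_labels, SelfOrganizingCloud):
        check_is_fitted(cvset_or_labels, "labels_")
        labels = cvset_or_labels.labels_
    else:
        labels = np.asarray(cvset_or_labels)
    return (labels[:, None] == labels[None, :]).astype(int)


def inherence_distance_correlation(cvset_or_labels, dist) -> float:
    """Pearson correlation between the inherence matrix and a distance
    matrix over the off-diagonal upper triangle.

    Same-cluster pairs sit at small distances when the clustering matches
    the geometry, so good correspondence shows up as a negative value.
    """
    from .distmantel import DistanceMatrix  # local import avoids a cycle

    inh = inherence_matrix(cvset_or_labels)
    if isinstance(dist, DistanceMatrix):
        d = dist.values.to_numpy(dtype=float)
    elif isinstance(dist, pd.DataFrame):
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
    if d.shape != inh.shape:
        raise ValueError(
            f"size mismatch: inherence {inh.shape} vs distance {d.shape}"
        )
    iu = np.triu_indices(len(inh), k=1)
    a, b = inh[iu].astype(float), d[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: constant upper triangle")
    return float(np.corrcoef(a, b)[0, 1])
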