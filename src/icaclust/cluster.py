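"""Ward hierarchical clustering with Mojena's stopping rule, the two-step
ICA-then-cluster estimator, and a k-means baseline.

Ward's minimum-variance method merges, at each of the m-1 agglomeration
stages, the pair of clusters (A, B) whose merge least increases the
within-group error sum of squares:

    I_AB = n_A n_B / (n_A + n_B) * ||ybar_A - ybar_B||^2

The fusion heights alpha_1 <= alpha_2 <= ... <= alpha_{m-1} are these
increments.  Mojena's rule selects the partition just before the first
"unusually large" fusion: the first stage j with alpha_j > mean(alpha) +
c * sd(alpha) yields k = m - j + 1 clusters.  The constant c defaults to 3.50,
the value recommended in Mojena's original evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .ica import ICADecomposition, TemporalICA, _as_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "MojenaResult",
    "ward_linkage",
    "mojena_select",
    "cut_dendrogram",
    "relabel_by_size",
    "WardMojena",
    "ICAClust",
    "icaclust",
    "kmeans_baseline",
]


@dataclass
class Dendrogram:
    """Ward merge history.

    ``linkage_matrix`` is the standard (m-1, 4) agglomeration encoding (left
    node, right node, height, size) with heights on the Euclidean-distance
    scale used by standard dendrogram tooling; ``heights`` are the same merges
    expressed as within-group sum-of-squares increments I_AB (the fusion
    levels used by Mojena's rule).  The two height scales are related by
    I = h^2 / 2, a strictly increasing map, so the merge order is identical.
    """

    linkage_matrix: np.ndarray
    heights: np.ndarray
    leaf_ids: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def n_merges(self) -> int:
        return self.linkage_matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "left": self.linkage_matrix[:, 0].astype(int),
                "right": self.linkage_matrix[:, 1].astype(int),
                "height": self.heights,
                "size": self.linkage_matrix[:, 3].astype(int),
            }
        )


@dataclass
class MojenaResult:
    alpha_mean: float
    alpha_sd: float
    c: float
    threshold: float
    selected_k: int
    triggering_stage: int | None


def ward_linkage(points) -> Dendrogram:
    """Agglomerate row vectors by Ward's minimum-variance method.

    Fusion heights are reported as the error-sum-of-squares increments I_AB;
    they are non-decreasing (Ward linkage is monotone).
    """
    X, ids, _ = _as_matrix(points)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points to cluster")
    if not np.isfinite(X).all():
        raise ValueError("points contain non-finite entries")
    Z = linkage(X, method="ward")
    heights = Z[:, 2] ** 2 / 2.0
    return Dendrogram(linkage_matrix=Z, heights=heights, leaf_ids=ids)


def mojena_select(dendrogram: Dendrogram, c: float = 3.50) -> MojenaResult:
    """Select the number of clusters by Mojena's upper-tail rule.

    The mean and sample standard deviation (n-1 denominator) are taken over
    all m-1 fusion heights; scanning merges from first to last, the first
    stage j whose height exceeds mean + c*sd selects k = m - j + 1 clusters
    (the partition in force just before that merge).  If no fusion exceeds the
    threshold the whole data set is taken as a single cluster, with a warning.
    """
    alphas = np.asarray(dendrogram.heights, dtype=float)
    if alphas.size < 2:
        raise ValueError("Mojena's rule needs at least 2 fusion levels (m >= 3)")
    mean = float(np.mean(alphas))
    sd = float(np.std(alphas, ddof=1))
    threshold = mean + c * sd
    exceed = np.nonzero(alphas > threshold)[0]
    m = dendrogram.n_leaves
    if exceed.size == 0:
        warnings.warn(
            f"no fusion level exceeds the Mojena threshold {threshold:.4g} "
            f"(c={c}); falling back to a single cluster",
            RuntimeWarning,
        )
        return MojenaResult(mean, sd, c, threshold, selected_k=1, triggering_stage=None)
    stage = int(exceed[0]) + 1  # 1-based stage index
    selected_k = m - stage + 1
    return MojenaResult(mean, sd, c, threshold, selected_k=selected_k, triggering_stage=stage)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Flat labels (1..k, relabelled by decreasing cluster size) for the
    k-cluster partition of the merge history."""
    if not 1 <= k <= dendrogram.n_leaves:
        raise ValueError(f"k must be in [1, {dendrogram.n_leaves}]")
    raw = fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    return relabel_by_size(raw)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Rename cluster labels to 1..k in order of decreasing size (ties broken
    by first appearance) for reproducible reporting."""
    labels = np.asarray(labels)
    uniq, first_pos, counts = np.unique(labels, return_index=True, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], first_pos[i]))
    mapping = {uniq[i]: rank + 1 for rank, i in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


class WardMojena(ClusterMixin, BaseEstimator):
    """Ward agglomerative clustering with automatic cluster-count selection.

    Parameters
    ----------
    c : float
        Mojena's constant; larger values demand a more extreme fusion jump and
        therefore never select more clusters than smaller values.

    Attributes (after fit)
    ----------------------
    labels_ : (m,) int array, clusters named 1..k by decreasing size
    n_clusters_ : int
    dendrogram_ : Dendrogram
    mojena_ : MojenaResult
    """

    def __init__(self, c: float = 3.50):
        self.c = c

    def fit(self, X, y=None):
        self.dendrogram_ = ward_linkage(X)
        self.mojena_ = mojena_select(self.dendrogram_, c=self.c)
        self.n_clusters_ = self.mojena_.selected_k
        self.labels_ = cut_dendrogram(self.dendrogram_, self.n_clusters_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class ICAClust(ClusterMixin, BaseEstimator):
    """Two-step clustering of gene expression time series.

    Step 1 decomposes the genes x time matrix into statistically independent
    components (FastICA after PCA whitening), giving each gene a k-vector of
    component scores; step 2 clusters the score vectors with Ward's method and
    selects the number of clusters with Mojena's rule.  Working on independent
    component scores rather than raw time columns respects the serial
    dependence between adjacent time points and makes no distributional
    assumption about the (count-valued) expression data.

    Parameters
    ----------
    c : float, default 3.50
        Mojena's constant.
    n_components : int or None
        Number of independent components; ``None`` keeps the full dimension
        (one component per time point).
    max_iter, tol : FastICA fixed-point iteration controls.
    random_state : seed for the FastICA initialisation.

    Attributes (after fit)
    ----------------------
    labels_ : (m,) int array (1..k, decreasing size)
    n_clusters_ : int
    decomposition_ : ICADecomposition
    dendrogram_ : Dendrogram
    mojena_ : MojenaResult

    Examples
    --------
    >>> model = ICAClust(c=3.5, random_state=0).fit(series)   # doctest: +SKIP
    >>> model.n_clusters_, model.labels_[:5]                  # doctest: +SKIP
    """

    def __init__(
        self,
        c: float = 3.50,
        n_components: int | None = None,
        max_iter: int = 200,
        tol: float = 1e-4,
        random_state: int | None = 0,
    ):
        self.c = c
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        ica = TemporalICA(
            n_components=self.n_components,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(X)
        self.decomposition_ = ica.decomposition_
        ward = WardMojena(c=self.c).fit(self.decomposition_.scores)
        self.dendrogram_ = ward.dendrogram_
        self.mojena_ = ward.mojena_
        self.n_clusters_ = ward.n_clusters_
        self.labels_ = ward.labels_
        logger.info(
            "ICAClust: k=%d clusters (Mojena c=%.2f, threshold %.4g)",
            self.n_clusters_,
            self.c,
            self.mojena_.threshold,
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def icaclust(
    series,
    c: float = 3.50,
    seed: int | None = 0,
    n_components: int | None = None,
) -> tuple[np.ndarray, ICADecomposition, Dendrogram, MojenaResult]:
    """Run the full two-step pipeline; returns (labels, decomposition,
    dendrogram, mojena result)."""
    model = ICAClust(c=c, n_components=n_components, random_state=seed).fit(series)
    return model.labels_, model.decomposition_, model.dendrogram_, model.mojena_


def kmeans_baseline(series, k: int, seed: int | None = 0, n_init: int = 10) -> np.ndarray:
    """k-means reference clustering on the raw series rows.

    Lloyd iterations from ``n_init`` k-means++ starts, best by within-cluster
    sum of squares; labels renamed 1..k by decreasing size.  Unlike the
    two-step method, k must be supplied.
    """
    X, _, _ = _as_matrix(series)
    if not 2 <= k <= X.shape[0]:
        raise ValueError(f"k must be in [2, {X.shape[0]}]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    return relabel_by_size(km.fit_predict(X) + 1)
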