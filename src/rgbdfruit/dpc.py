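"""Density-peak clustering of block features with KDE-smoothed density.

Cluster centers are points that combine high local density rho with a
large separation delta from any denser point; every other point inherits
the label of its nearest denser neighbor in one pass — no iteration, no
random initialization, fully deterministic.

Density is estimated by a Gaussian kernel density estimate rather than the
classic hard cutoff count, removing the manually chosen cutoff distance
d_c (the hard-count variant is kept for comparison).  Center selection is
automatic by double sorting: take the ``n_density_top`` densest points,
keep the ``n_delta_top`` of them with the largest delta.  Finally clusters
are ranked by the pixel coverage of their member blocks and only the top
``n_keep_clusters`` survive; members of pruned clusters are reattached
along their nearest-denser-neighbor chains.

Ties in density are broken by point index (lower index counts as denser)
throughout, so every quantity is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import InputError, InternalConsistencyError, ParameterError


@dataclass
class SelectionParams:
    """Double-sort center selection counts.

    ``n_density_top`` gates candidates to the densest blocks;
    ``n_delta_top`` picks the most separated among them (this is what
    limits the cluster count, so it should be of the order of the number
    of feature modes in the scene: fruit, lit foliage, shaded foliage,
    branches); ``n_keep_clusters`` clusters survive coverage pruning.
    """

    n_density_top: int = 60
    n_delta_top: int = 4
    n_keep_clusters: int = 4

    def __post_init__(self):
        if min(self.n_density_top, self.n_delta_top,
               self.n_keep_clusters) < 1:
            raise ParameterError("selection counts must be positive")
        if self.n_delta_top > self.n_density_top:
            raise ParameterError("n_delta_top must be <= n_density_top")
        if self.n_keep_clusters > self.n_delta_top:
            raise ParameterError("n_keep_clusters must be <= n_delta_top")


@dataclass
class DpcState:
    """Everything the clustering computed, for inspection and plotting."""

    points: np.ndarray
    dist: np.ndarray
    rho: np.ndarray
    delta: np.ndarray
    nn_higher: np.ndarray  # -1 for the global density maximum
    centers: np.ndarray
    labels: np.ndarray
    sigma: float


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix over the feature points."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or len(points) < 2:
        raise InputError("need an (n >= 2, dim) point array")
    if not np.isfinite(points).all():
        raise InputError("non-finite feature coordinate")
    return squareform(pdist(points, metric="euclidean"))


def silverman_sigma(points: np.ndarray) -> float:
    """Silverman's rule bandwidth for a 2-D cloud: mean per-axis std times
    n^(-1/6)."""
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    spread = points.std(axis=0, ddof=1).mean()
    if spread <= 0:
        return 1.0
    return float(spread * n ** (-1.0 / 6.0))


def kde_density(points: np.ndarray, sigma: float, h: float = 1.0
                ) -> np.ndarray:
    """Gaussian-KDE local density.

    rho_i = 1/(n h) * sum_j K((x_i-x_j)/h, (y_i-y_j)/h) with
    K(x, y) = exp(-(x^2+y^2) / (2 sigma^2)) / (2 pi sigma^2).
    The self term j = i is included.  ``h`` and ``sigma`` are redundant
    scale parameters; the pipeline fixes h = 1 and exposes sigma.
    """
    if sigma <= 0 or h <= 0:
        raise ParameterError("sigma and h must be positive")
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    sq = (diff ** 2).sum(axis=-1)
    kernel = np.exp(-sq / (2.0 * (sigma * h) ** 2)) / (2.0 * np.pi * sigma ** 2)
    return kernel.sum(axis=1) / (n * h)


def cutoff_density(dist: np.ndarray, d_c: float) -> np.ndarray:
    """Classic hard-cutoff density: rho_i = #{j != i : d_ij <= d_c}."""
    if d_c <= 0:
        raise ParameterError("d_c must be positive")
    dist = np.asarray(dist)
    counts = (dist <= d_c).sum(axis=1) - 1  # exclude the self distance
    return counts.astype(np.float64)


def delta_separation(dist: np.ndarray, rho: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Separation delta_i = distance to the nearest denser point.

    For the global density maximum delta is the distance to the farthest
    point and ``nn_higher`` is -1.  Exact density ties are broken by index
    (the lower index counts as denser).
    """
    dist = np.asarray(dist, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    if not np.isfinite(rho).all():
        raise InputError("non-finite density")
    n = len(rho)
    order = np.lexsort((np.arange(n), -rho))  # descending rho, index ties
    delta = np.empty(n)
    nn_higher = np.full(n, -1, dtype=np.int64)
    top = order[0]
    delta[top] = dist[top].max()
    for pos in range(1, n):
        i = order[pos]
        denser = order[:pos]
        j_local = np.argmin(dist[i, denser])
        nn_higher[i] = denser[j_local]
        delta[i] = dist[i, denser[j_local]]
    return delta, nn_higher


def double_sort_select(rho: np.ndarray, delta: np.ndarray,
                       params: SelectionParams) -> np.ndarray:
    """Automatic center selection by double sorting.

    Sort by density descending and keep the first ``n_density_top``
    points; sort those by delta descending and keep the first
    ``n_delta_top``.  Ties broken by index; the result is ordered by
    descending delta.
    """
    rho = np.asarray(rho, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    n = len(rho)
    if n < params.n_density_top:
        raise ParameterError(
            f"only {n} points but n_density_top={params.n_density_top}; "
            "reduce the selection counts")
    order_rho = np.lexsort((np.arange(n), -rho))
    top = order_rho[:params.n_density_top]
    order_delta = top[np.lexsort((top, -delta[top]))]
    return order_delta[:params.n_delta_top]


def assign_labels(nn_higher: np.ndarray, rho: np.ndarray,
                  centers: np.ndarray,
                  dist: np.ndarray | None = None) -> np.ndarray:
    """Chain assignment: visit points by decreasing density; every
    non-center inherits the label of its nearest denser neighbor.

    If the global density maximum was not selected as a center its chain
    has no labeled terminus; with ``dist`` given it is attached to its
    nearest center, otherwise this raises.
    """
    centers = np.asarray(centers, dtype=np.int64)
    if len(centers) == 0:
        raise ParameterError("centers must be non-empty")
    n = len(rho)
    labels = np.full(n, -1, dtype=np.int64)
    labels[centers] = np.arange(len(centers))
    order = np.lexsort((np.arange(n), -np.asarray(rho, dtype=np.float64)))
    for i in order:
        if labels[i] >= 0:
            continue
        j = nn_higher[i]
        if j < 0 or labels[j] < 0:
            if dist is None:
                raise InternalConsistencyError(
                    f"assignment chain of point {i} does not reach a center")
            labels[i] = labels[centers[np.argmin(dist[i, centers])]]
        else:
            labels[i] = labels[j]
    return labels


def coverage_ranking(labels: np.ndarray, block_sizes: np.ndarray
                     ) -> np.ndarray:
    """Cluster ids ordered by total pixel coverage, largest first (ties by
    lower cluster id)."""
    labels = np.asarray(labels, dtype=np.int64)
    sizes = np.asarray(block_sizes, dtype=np.int64)
    n_clusters = labels.max() + 1
    coverage = np.bincount(labels, weights=sizes, minlength=n_clusters)
    return np.lexsort((np.arange(n_clusters), -coverage))


def prune_clusters(labels: np.ndarray, block_sizes: np.ndarray,
                   n_keep_clusters: int,
                   nn_higher: np.ndarray | None = None,
                   dist: np.ndarray | None = None) -> np.ndarray:
    """Keep the ``n_keep_clusters`` clusters with the largest pixel
    coverage; reattach members of pruned clusters.

    A pruned member follows its nearest-denser-neighbor chain to the first
    ancestor in a kept cluster; if the chain never reaches one, it joins
    the kept cluster of its nearest point in feature space (requires
    ``dist``).
    """
    labels = np.asarray(labels, dtype=np.int64).copy()
    n_clusters = labels.max() + 1
    if n_clusters <= n_keep_clusters:
        if n_clusters < n_keep_clusters:
            warnings.warn(
                f"only {n_clusters} clusters present, keeping all",
                stacklevel=2)
        return labels
    ranking = coverage_ranking(labels, block_sizes)
    kept = set(int(k) for k in ranking[:n_keep_clusters])
    is_kept = np.array([lab in kept for lab in labels])
    kept_points = np.nonzero(is_kept)[0]
    for i in np.nonzero(~is_kept)[0]:
        new_label = -1
        if nn_higher is not None:
            j = i
            seen = 0
            while j >= 0 and seen <= len(labels):
                if labels[j] in kept and is_kept[j]:
                    new_label = labels[j]
                    break
                j = nn_higher[j]
                seen += 1
        if new_label < 0:
            if dist is None:
                raise ParameterError(
                    "pruned chain has no kept ancestor and no dist matrix "
                    "was provided")
            new_label = labels[kept_points[np.argmin(dist[i, kept_points])]]
        labels[i] = new_label
    return labels


def cluster_blocks(points: np.ndarray, block_sizes: np.ndarray,
                   sigma: float | None = None,
                   params: SelectionParams | None = None,
                   density: str = "kde", d_c: float | None = None
                   ) -> DpcState:
    """Full clustering stage over block feature points.

    ``density`` selects the KDE estimator (default) or the classic
    ``"cutoff"`` count (then ``d_c`` defaults to 2% of the max pairwise
    distance).  Selection counts are clamped to the number of points so
    small images degrade gracefully.
    """
    params = params or SelectionParams()
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    dist = pairwise_distances(points)
    if sigma is None:
        sigma = silverman_sigma(points)
    if density == "kde":
        rho = kde_density(points, sigma=sigma)
    elif density == "cutoff":
        if d_c is None:
            d_c = max(0.02 * dist.max(), 1e-9)
        rho = cutoff_density(dist, d_c)
    else:
        raise ParameterError(f"unknown density estimator {density!r}")
    delta, nn_higher = delta_separation(dist, rho)
    eff = SelectionParams(
        n_density_top=min(params.n_density_top, n),
        n_delta_top=min(params.n_delta_top, n),
        n_keep_clusters=min(params.n_keep_clusters, n),
    )
    centers = double_sort_select(rho, delta, eff)
    labels = assign_labels(nn_higher, rho, centers, dist=dist)
    labels = prune_clusters(labels, block_sizes, eff.n_keep_clusters,
                            nn_higher=nn_higher, dist=dist)
    return DpcState(points=points, dist=dist, rho=rho, delta=delta,
                    nn_higher=nn_higher, centers=centers, labels=labels,
                    sigma=float(sigma))
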