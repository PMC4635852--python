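"""Sample-level subtype discovery.

The procedure is the classic unsupervised chain for expression cohorts:

1. embed samples with classical (Torgerson) multidimensional scaling and
   drop outliers whose distance to the cohort center exceeds the mean by
   more than ``z_threshold`` standard deviations;
2. hierarchically cluster the retained samples;
3. score candidate cluster counts with three internal validity indices
   (connectivity: lower is better; Dunn and mean silhouette: higher is
   better) and let the indices vote for the number of subtypes.

Everything here is deterministic given the input and configuration: ties
in neighbor ranks break by sample order and the vote breaks toward the
smallest k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EmbeddingReport",
    "ClusterSolution",
    "ValidityIndices",
    "pairwise_distances",
    "classical_mds",
    "flag_outliers",
    "hierarchical_cluster",
    "cut_tree",
    "connectivity_index",
    "dunn_index",
    "silhouette_index",
    "select_k",
]

DISTANCES = ("euclidean", "one_minus_pearson")
LINKAGES = ("average", "complete", "ward")


def pairwise_distances(observations: np.ndarray, metric: str = "euclidean"
                       ) -> np.ndarray:
    """Square distance matrix between rows of *observations*.

    ``one_minus_pearson`` is 1 minus the Pearson correlation of the rows,
    the customary expression-profile dissimilarity (range [0, 2]).
    """
    observations = np.asarray(observations, dtype=float)
    if metric == "euclidean":
        return squareform(pdist(observations, metric="euclidean"))
    if metric == "one_minus_pearson":
        dist = 1.0 - np.corrcoef(observations)
        np.fill_diagonal(dist, 0.0)
        return np.clip(dist, 0.0, None)
    raise ValueError(f"unknown distance {metric!r}; choose from {DISTANCES}")


def _check_square_distances(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix contains non-finite entries")
    if np.any(dist < 0):
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal is not zero")
    return dist


# ---------------------------------------------------------------------------
# classical MDS and outlier flagging

def classical_mds(dist_matrix: np.ndarray, d: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix to *d* dimensions.

    Double-centers -1/2 D^2, takes the top-*d* eigenvectors scaled by the
    square root of their eigenvalues.  Axes whose eigenvalue is negative
    (non-Euclidean input) are zeroed with a warning.
    """
    dist = _check_square_distances(dist_matrix)
    n = dist.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension {d} outside [1, {n}]")
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gram = -0.5 * centering @ (dist ** 2) @ centering
    eigvals, eigvecs = np.linalg.eigh((gram + gram.T) / 2.0)
    order = np.argsort(eigvals)[::-1][:d]
    top_vals = eigvals[order]
    top_vecs = eigvecs[:, order]
    # eigenvalues within numerical noise of zero are zero, not evidence of
    # non-Euclidean input
    tol = max(eigvals.max(), 0.0) * 1e-9 + 1e-12
    if np.any(top_vals < -tol):
        warnings.warn(
            f"{int((top_vals < -tol).sum())} of the top {d} eigenvalues are "
            "negative (non-Euclidean distances); those axes are set to zero",
            stacklevel=2)
    scale = np.sqrt(np.clip(top_vals, 0.0, None))
    return top_vecs * scale


@dataclass
class EmbeddingReport:
    """MDS coordinates with center-distance z-scores and outlier flags."""

    sample_ids: list[str]
    coordinates: np.ndarray
    center: np.ndarray
    center_mode: str
    distance: np.ndarray
    zscore: np.ndarray
    z_threshold: float
    outliers: set[str]
    degenerate: bool = False

    @property
    def retained_sample_ids(self) -> list[str]:
        return [s for s in self.sample_ids if s not in self.outliers]


def flag_outliers(coordinates: np.ndarray, sample_ids,
                  center_mode: str = "medoid",
                  z_threshold: float = 2.0) -> EmbeddingReport:
    """Flag samples whose distance to the cohort center is more than
    *z_threshold* standard deviations above the mean distance.

    The center is either the medoid (sample minimizing summed distance to
    all others; robust to the very outliers being hunted) or the centroid.
    Flagging is a single pass — there is no re-embedding iteration.  If all
    distances are identical the spread is degenerate and nothing is flagged.
    """
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    sample_ids = list(sample_ids)
    n = coords.shape[0]
    if n != len(sample_ids):
        raise ValueError("coordinate rows and sample ids differ in length")
    if n < 4:
        raise ValueError("outlier flagging needs at least 4 samples")
    if center_mode == "medoid":
        pair = squareform(pdist(coords))
        center = coords[np.argmin(pair.sum(axis=1))]
    elif center_mode == "centroid":
        center = coords.mean(axis=0)
    else:
        raise ValueError(f"center_mode must be 'medoid' or 'centroid', got {center_mode!r}")
    distance = np.linalg.norm(coords - center, axis=1)
    spread = distance.std(ddof=1)
    if spread == 0:
        zscore = np.zeros(n)
        return EmbeddingReport(sample_ids, coords, center, center_mode,
                               distance, zscore, z_threshold, set(),
                               degenerate=True)
    zscore = (distance - distance.mean()) / spread
    outliers = {s for s, z in zip(sample_ids, zscore) if z > z_threshold}
    return EmbeddingReport(sample_ids, coords, center, center_mode,
                           distance, zscore, z_threshold, outliers)


# ---------------------------------------------------------------------------
# hierarchical clustering

def hierarchical_cluster(observations: np.ndarray,
                         distance: str = "one_minus_pearson",
                         linkage: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) over the rows of
    *observations*.

    Ward linkage requires Euclidean distances; average and complete accept
    either metric.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distances")
    dist = pairwise_distances(observations, distance)
    condensed = squareform(dist, checks=False)
    if not np.all(np.isfinite(condensed)):
        raise ValueError("non-finite distance between observations")
    return sch.linkage(condensed, method=linkage)


def cut_tree(merge_tree: np.ndarray, k: int) -> np.ndarray:
    """Cut the merge tree into exactly *k* clusters.

    Labels are renumbered 1..k by order of first appearance, so cluster 1
    always contains the first sample.
    """
    n = merge_tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    raw = sch.cut_tree(merge_tree, n_clusters=k).ravel()
    mapping: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return labels


# ---------------------------------------------------------------------------
# cluster validity indices

def _check_labels(dist: np.ndarray, labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != dist.shape[0]:
        raise ValueError("labels and distance matrix differ in length")
    return labels


def connectivity_index(dist_matrix: np.ndarray, labels, L: int = 10) -> float:
    """Connectivity penalty: for each sample, sum 1/j over the neighbor
    ranks j = 1..L whose j-th nearest neighbor lies in a different cluster.

    Lower is better (0 when every sample's L nearest neighbors are
    co-clustered).  Distance ties break deterministically by sample order.
    """
    dist = _check_square_distances(dist_matrix)
    labels = _check_labels(dist, labels)
    n = dist.shape[0]
    L = min(L, n - 1)
    total = 0.0
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        neighbors = [j for j in order if j != i][:L]
        for rank, j in enumerate(neighbors, start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def dunn_index(dist_matrix: np.ndarray, labels) -> float:
    """Dunn index: minimum between-cluster (single-linkage) distance over
    maximum within-cluster diameter; higher is better.

    A clustering of only singletons has zero maximum diameter, giving
    ``inf`` — perfectly separated by this criterion's arithmetic.
    """
    dist = _check_square_distances(dist_matrix)
    labels = _check_labels(dist, labels)
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    masks = [labels == u for u in unique]
    max_diam = 0.0
    for m in masks:
        sub = dist[np.ix_(m, m)]
        if sub.shape[0] > 1:
            max_diam = max(max_diam, float(sub.max()))
    min_inter = math.inf
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            min_inter = min(min_inter, float(dist[np.ix_(masks[a], masks[b])].min()))
    if max_diam == 0.0:
        return math.inf
    return min_inter / max_diam


def silhouette_index(dist_matrix: np.ndarray, labels) -> float:
    """Mean silhouette width: per sample (b - a)/max(a, b) with a the mean
    intra-cluster distance and b the smallest mean distance to another
    cluster.  Singleton samples contribute 0.  Result lies in [-1, 1].
    """
    dist = _check_square_distances(dist_matrix)
    labels = _check_labels(dist, labels)
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    masks = {u: labels == u for u in unique}
    widths = np.zeros(dist.shape[0])
    for i in range(dist.shape[0]):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton: silhouette 0 by convention
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, masks[u]].mean() for u in unique if u != labels[i])
        widths[i] = (b - a) / max(a, b)
    return float(widths.mean())


@dataclass(frozen=True)
class ValidityIndices:
    connectivity: float
    dunn: float
    silhouette: float


@dataclass
class ClusterSolution:
    """Merge tree plus per-k labels, validity indices, and the voted k."""

    merge_tree: np.ndarray = field(repr=False)
    labels_by_k: dict[int, np.ndarray] = field(repr=False)
    indices_by_k: dict[int, ValidityIndices]
    selection_votes: dict[str, int]
    selected_k: int

    @property
    def labels(self) -> np.ndarray:
        return self.labels_by_k[self.selected_k]


def select_k(dist_matrix: np.ndarray, merge_tree: np.ndarray,
             k_range=range(2, 7), L: int = 10) -> ClusterSolution:
    """Cut the tree at each k in *k_range*, score all three validity
    indices, and select k by majority vote (connectivity votes for its
    minimum; Dunn and silhouette for their maxima; ties toward smallest k).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    dist = _check_square_distances(dist_matrix)
    labels_by_k: dict[int, np.ndarray] = {}
    indices_by_k: dict[int, ValidityIndices] = {}
    for k in ks:
        labels = cut_tree(merge_tree, k)
        labels_by_k[k] = labels
        indices_by_k[k] = ValidityIndices(
            connectivity=connectivity_index(dist, labels, L=L),
            dunn=dunn_index(dist, labels),
            silhouette=silhouette_index(dist, labels),
        )
    votes = {
        "connectivity": min(ks, key=lambda k: (indices_by_k[k].connectivity, k)),
        "dunn": max(ks, key=lambda k: (indices_by_k[k].dunn, -k)),
        "silhouette": max(ks, key=lambda k: (indices_by_k[k].silhouette, -k)),
    }
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.values())
    selected_k = min(k for k, c in counts.items() if c == best)
    return ClusterSolution(merge_tree, labels_by_k, indices_by_k, votes, selected_k)
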