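"""Temporal pattern extraction: K-means, hierarchical clustering, DTW, scree.

Clustering operates on complete (preprocessed) matrices whose rows are
temporal profiles. K selection is advisory: `wcss_scree` emits the WCSS
table for a range of K and `elbow_k` offers a second-difference heuristic,
but the user picks K by inspecting the patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import ParameterError

DEFAULT_RESTARTS = 20
DEFAULT_SEED = 20200603


@dataclass
class ClusteringResult:
    """Labels (1..K), per-cluster mean profiles and the WCSS objective."""

    labels: np.ndarray            # (m,) ints in 1..K
    centers: np.ndarray           # (K, n) cluster mean profiles
    K: int
    wcss: float
    method: str                   # "kmeans" | "hierarchical"
    distance: str = "euclidean"
    linkage: str | None = None
    seed: int | None = None
    restarts: int | None = None

    def to_dict(self) -> dict:
        return {
            "K": self.K, "wcss": self.wcss, "method": self.method,
            "distance": self.distance, "linkage": self.linkage,
            "seed": self.seed, "restarts": self.restarts,
        }


@dataclass
class ScreeTable:
    """WCSS per candidate K, for scree-plot inspection."""

    rows: list = field(default_factory=list)  # (K, wcss, restarts, seed)

    def add(self, K, wcss, restarts, seed):
        self.rows.append(
            {"K": int(K), "wcss": float(wcss), "restarts": int(restarts),
             "seed": int(seed)}
        )

    @property
    def K_values(self):
        return [r["K"] for r in self.rows]

    @property
    def wcss_values(self):
        return [r["wcss"] for r in self.rows]


def _extract_values(matrix) -> np.ndarray:
    X = matrix.values if hasattr(matrix, "values") else matrix
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ParameterError("clustering requires a complete matrix; "
                             "preprocess first")
    return X


def _canonicalize(X: np.ndarray, labels0: np.ndarray, K: int):
    """Renumber clusters by descending size (ties: first-row index), recompute
    centers as coordinate-wise means and the WCSS objective."""
    sizes = np.bincount(labels0, minlength=K)
    first = np.full(K, X.shape[0])
    for i, lab in enumerate(labels0):
        if i < first[lab]:
            first[lab] = i
    order = sorted(range(K), key=lambda k: (-sizes[k], first[k]))
    remap = np.empty(K, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    labels = remap[labels0]
    centers = np.vstack([X[labels == k + 1].mean(axis=0) for k in range(K)])
    wcss = float(np.sum((X - centers[labels - 1]) ** 2))
    return labels, centers, wcss


def kmeans_cluster(matrix, K: int, restarts: int = DEFAULT_RESTARTS,
                   seed: int = DEFAULT_SEED, standardize: bool = False,
                   init=None) -> ClusteringResult:
    """Lloyd's K-means with k-means++ seeding, best of `restarts` by WCSS.

    `init` may supply explicit starting centers (a (K, n) array), in which
    case a single deterministic run from those centers is performed — used by
    the jackstraw resampling loop.
    """
    X = _extract_values(matrix)
    m = X.shape[0]
    if not 1 <= K <= m:
        raise ParameterError(f"K must lie in [1, {m}], got {K}")
    if standardize:
        sd = X.std(axis=1, keepdims=True)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    if init is not None:
        km = KMeans(n_clusters=K, init=np.asarray(init, dtype=float),
                    n_init=1, algorithm="lloyd", random_state=0)
    else:
        km = KMeans(n_clusters=K, init="k-means++", n_init=int(restarts),
                    algorithm="lloyd", random_state=int(seed) % (2 ** 31))
    labels0 = km.fit_predict(X)
    # guard: repair any empty cluster by splitting off the worst-fit point
    present = np.unique(labels0)
    if len(present) < K:
        centers = km.cluster_centers_
        for k in range(K):
            if k not in present:
                resid = np.sum((X - centers[labels0]) ** 2, axis=1)
                worst = int(np.argmax(resid))
                labels0[worst] = k
                present = np.unique(labels0)
    labels, centers, wcss = _canonicalize(X, labels0, K)
    return ClusteringResult(labels, centers, K, wcss, method="kmeans",
                            distance="euclidean", seed=int(seed),
                            restarts=int(restarts))


# ---------------------------------------------------------------------------
# Dynamic time warping


def dtw_distance(a, b, window: int | None = None) -> float:
    """Classical DTW with squared pointwise cost and optional Sakoe–Chiba band.

    Steps are {match, insert, delete}; the returned value is the square root
    of the terminal cumulative cost, so it coincides with the Euclidean
    distance when the optimal path is the diagonal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ParameterError("DTW operates on 1-D series")
    if len(a) != len(b):
        raise ParameterError("series must have equal length")
    n = len(a)
    if window is not None:
        window = int(window)
        if window < 0:
            raise ParameterError("window must be >= 0")
        if window < abs(len(a) - len(b)):
            raise ParameterError("window too small to connect the corners")
    D = np.full((n + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        lo = 1 if window is None else max(1, i - window)
        hi = n if window is None else min(n, i + window)
        for j in range(lo, hi + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            D[i, j] = cost + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return float(np.sqrt(D[n, n]))


def dtw_distance_matrix(X: np.ndarray, window: int | None = None) -> np.ndarray:
    """Condensed pairwise DTW distances (same layout as scipy's pdist)."""
    m = X.shape[0]
    out = np.empty(m * (m - 1) // 2)
    idx = 0
    for i in range(m):
        for j in range(i + 1, m):
            out[idx] = dtw_distance(X[i], X[j], window=window)
            idx += 1
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering


def hierarchical_cluster(matrix, K: int, distance: str = "euclidean",
                         linkage: str = "average",
                         window: int | None = None) -> ClusteringResult:
    """Agglomerative clustering cut at K groups.

    Distances are Euclidean or DTW; linkage is average, complete or ward
    (ward requires Euclidean distances). Centers are per-cluster coordinate
    means over the time axis regardless of the distance used, since the
    downstream membership test regresses on mean profiles.
    """
    X = _extract_values(matrix)
    m = X.shape[0]
    if not 1 <= K <= m:
        raise ParameterError(f"K must lie in [1, {m}], got {K}")
    if distance not in ("euclidean", "dtw"):
        raise ParameterError(f"unknown distance: {distance!r}")
    if linkage not in ("average", "complete", "ward"):
        raise ParameterError(f"unknown linkage: {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise ParameterError("ward linkage requires euclidean distance")
    if distance == "euclidean":
        condensed = pdist(X, metric="euclidean")
    else:
        condensed = dtw_distance_matrix(X, window=window)
    Z = scipy_linkage(condensed, method=linkage)
    labels0 = fcluster(Z, t=K, criterion="maxclust") - 1
    # fcluster may merge ties; renumber to consecutive 0..K'-1
    uniq = np.unique(labels0)
    labels0 = np.searchsorted(uniq, labels0)
    labels, centers, wcss = _canonicalize(X, labels0, len(uniq))
    return ClusteringResult(labels, centers, len(uniq), wcss,
                            method="hierarchical", distance=distance,
                            linkage=linkage)


# ---------------------------------------------------------------------------
# Scree support for choosing K


def wcss_scree(matrix, K_range, restarts: int = DEFAULT_RESTARTS,
               seed: int = DEFAULT_SEED) -> ScreeTable:
    """WCSS of the best-of-`restarts` K-means fit for each K in `K_range`."""
    X = _extract_values(matrix)
    K_list = [int(k) for k in K_range]
    if len(set(K_list)) != len(K_list) or K_list != sorted(K_list):
        raise ParameterError("K_range values must be distinct and ascending")
    if max(K_list) > X.shape[0]:
        raise ParameterError("max K exceeds the number of variables")
    table = ScreeTable()
    for K in K_list:
        res = kmeans_cluster(X, K, restarts=restarts, seed=seed)
        table.add(K, res.wcss, restarts, seed)
    return table


def elbow_k(table: ScreeTable) -> int:
    """Advisory elbow: the K with the largest second difference of WCSS."""
    K = np.asarray(table.K_values)
    w = np.asarray(table.wcss_values)
    if len(K) < 3:
        raise ParameterError("elbow heuristic needs >= 3 K values")
    second = w[:-2] - 2 * w[1:-1] + w[2:]
    return int(K[1 + int(np.argmax(second))])
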