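"""In-repo k-means (Lloyd's algorithm with k-means++ restarts), elbow-curve
model selection, silhouette validation, and risk-ordering of cluster labels.

k-means is implemented here rather than delegated because the clustering is
the analytical core of the pipeline: the objective is the total
within-cluster sum of squares

    W(k) = sum_j sum_{x in S_j} ||x - c_j||^2,   c_j = mean of S_j,

minimized by alternating nearest-center assignment and center recomputation.
Determinism is explicit: restart ``r`` draws its k-means++ seeds from an
independent generator seeded ``seed + r``, and the best restart by final WSS
is returned.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import IndicatorTable
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterModel:
    """Result of one k-means fit.

    ``assignments`` holds 1-based cluster labels aligned with the row order
    of the fitted matrix; after :func:`rank_clusters_by_risk` label ``k`` is
    the highest-risk cluster.
    """

    theme: str
    k: int
    centers: np.ndarray  # (k, p)
    assignments: np.ndarray  # (n,) int labels in 1..k
    wss: float
    n_iter: int
    seed: int
    converged: bool
    risk_ordered: bool = False

    def members(self, label: int, countries: list[str] | None = None):
        idx = np.flatnonzero(self.assignments == label)
        if countries is None:
            return idx
        return frozenset(countries[i] for i in idx)


def _wss(X: np.ndarray, centers: np.ndarray, labels0: np.ndarray) -> float:
    return float(((X - centers[labels0]) ** 2).sum())


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first center uniform, later centers proportional to
    squared distance from the nearest chosen center."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j] = X[rng.integers(n)]
            continue
        centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Lloyd iterations until the assignment stabilizes.  An emptied cluster
    is reseeded with the point farthest from its assigned center."""
    n, k = X.shape[0], centers.shape[0]
    labels0 = np.full(n, -1)
    for it in range(1, max_iter + 1):
        d = cdist(X, centers, "sqeuclidean")
        new_labels = d.argmin(axis=1)  # ties -> lowest index, per argmin
        for j in range(k):
            members = X[new_labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                far = ((X - centers[new_labels]) ** 2).sum(axis=1).argmax()
                centers[j] = X[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels0):
            return labels0, centers, it, True
        labels0 = new_labels
    # final re-assignment so each point sits with its nearest center
    d = cdist(X, centers, "sqeuclidean")
    labels0 = d.argmin(axis=1)
    return labels0, centers, max_iter, False


def kmeans_fit(
    matrix: np.ndarray | IndicatorTable,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    max_iter: int = 300,
    theme: str = "",
) -> ClusterModel:
    """Best-of-restarts k-means on a standardized matrix.

    Parameters
    ----------
    matrix
        (n, p) array (or IndicatorTable, whose full value matrix is used);
        no missing cells, n >= k.
    k, seed, restarts, max_iter
        Restart ``r`` uses generator seed ``seed + r``; convergence is exact
        assignment stability with an iteration cap.
    """
    X = matrix.values.to_numpy(float) if isinstance(matrix, IndicatorTable) else np.asarray(matrix, float)
    if X.ndim != 2:
        raise ValidationError("matrix must be 2-D")
    if np.isnan(X).any():
        raise ValidationError("matrix contains missing cells; screen first")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if X.shape[0] < k:
        raise ValidationError(f"need at least k={k} rows, got {X.shape[0]}")
    best: tuple[float, np.ndarray, np.ndarray, int, bool] | None = None
    for r in range(max(1, restarts)):
        rng = np.random.default_rng(seed + r)
        centers = _kmeanspp(X, k, rng)
        labels0, centers, n_iter, conv = _lloyd(X, centers.copy(), max_iter)
        w = _wss(X, centers, labels0)
        if best is None or w < best[0] - 1e-12:
            best = (w, labels0, centers, n_iter, conv)
    w, labels0, centers, n_iter, conv = best
    return ClusterModel(
        theme=theme,
        k=k,
        centers=centers,
        assignments=labels0 + 1,
        wss=w,
        n_iter=n_iter,
        seed=seed,
        converged=conv,
    )


@dataclass(frozen=True)
class ElbowCurve:
    """WSS as a function of k, with the automatically chosen elbow."""

    k_values: tuple[int, ...]
    wss_values: tuple[float, ...]
    chosen_k: int


def elbow_curve(
    matrix: np.ndarray | IndicatorTable,
    k_min: int = 1,
    k_max: int = 6,
    seed: int = 0,
    restarts: int = 50,
) -> ElbowCurve:
    """Fit k-means over a range of k and locate the elbow.

    The elbow is the interior k maximizing the second forward difference of
    log-WSS — the point where the *relative* WSS reduction collapses.  The
    log scale makes the criterion invariant to the overall scale of the
    data; on the raw scale the second difference is dominated by the first
    merge of well-separated groups and systematically undershoots the true
    cluster count when the group centers are near-collinear.  With only two
    k values there is no interior point; ``k_min`` is returned with a
    warning.  Non-monotone WSS (possible with few restarts) is logged.
    """
    X = matrix.values.to_numpy(float) if isinstance(matrix, IndicatorTable) else np.asarray(matrix, float)
    if not (1 <= k_min < k_max <= X.shape[0]):
        raise ValidationError(f"need 1 <= k_min < k_max <= n rows, got [{k_min}, {k_max}]")
    ks = tuple(range(k_min, k_max + 1))
    wss = tuple(kmeans_fit(X, k, seed=seed, restarts=restarts).wss for k in ks)
    if any(b > a + 1e-9 for a, b in zip(wss, wss[1:])):
        logger.warning("elbow curve is not non-increasing; consider more restarts")
    if len(ks) < 3:
        logger.warning("elbow range has no interior point; reporting k_min=%d", k_min)
        return ElbowCurve(ks, wss, k_min)
    floor = max(max(wss) * 1e-12, 1e-300)
    logw = np.log(np.maximum(wss, floor))
    second = [logw[i - 1] - 2 * logw[i] + logw[i + 1] for i in range(1, len(ks) - 1)]
    chosen = ks[1 + int(np.argmax(second))]
    return ElbowCurve(ks, wss, chosen)


def silhouette(matrix: np.ndarray | IndicatorTable, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient, Euclidean distance.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the point's own cluster (excluding itself) and b(i) the smallest mean
    distance to another cluster; points in singleton clusters score 0.
    """
    X = matrix.values.to_numpy(float) if isinstance(matrix, IndicatorTable) else np.asarray(matrix, float)
    labels0 = np.asarray(assignments)
    uniq = np.unique(labels0)
    if len(uniq) < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    scores = np.zeros(n)
    sizes = {u: int((labels0 == u).sum()) for u in uniq}
    for i in range(n):
        own = labels0[i]
        if sizes[own] == 1:
            continue
        mask_own = labels0 == own
        a = D[i, mask_own].sum() / (sizes[own] - 1)
        b = min(D[i, labels0 == u].mean() for u in uniq if u != own)
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def rank_clusters_by_risk(
    model: ClusterModel,
    table: IndicatorTable,
    directions: dict[str, int],
) -> ClusterModel:
    """Relabel clusters 1..k in increasing severity, so label k is worst.

    Raw k-means labels are arbitrary; this fixes them by a severity score:
    per cluster, the mean over its countries of the direction-aligned
    z-scored theme variables (direction +1 = higher is worse).  Ties break
    by cluster size descending, then by original label.
    """
    spec = table.theme(model.theme) if model.theme else None
    cols = list(spec.variables) if spec else list(table.values.columns)
    missing = [c for c in cols if c not in directions]
    if missing:
        raise ConfigurationError(f"no severity direction configured for: {missing}")
    V = table.values.loc[:, cols].to_numpy(float)
    sd = V.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (V - V.mean(axis=0)) / sd
    signs = np.array([directions[c] for c in cols], float)
    severity_per_row = (Z * signs).mean(axis=1)
    stats = []
    for label in range(1, model.k + 1):
        idx = model.assignments == label
        stats.append((float(severity_per_row[idx].mean()), -int(idx.sum()), label))
    order = sorted(stats)  # ascending severity; ties -> larger cluster first, then label
    relabel = {old: new for new, (_, _, old) in enumerate(order, start=1)}
    new_assign = np.array([relabel[a] for a in model.assignments])
    new_centers = np.empty_like(model.centers)
    for old, new in relabel.items():
        new_centers[new - 1] = model.centers[old - 1]
    return replace(model, assignments=new_assign, centers=new_centers, risk_ordered=True)


def exhaustive_min_wss(X: np.ndarray, k: int) -> float:
    """Exact minimum WSS over all partitions into at most k non-empty
    clusters, by enumeration.  Exponential — for oracle use on tiny n only."""
    X = np.asarray(X, float)
    n = X.shape[0]
    best = np.inf
    for labels0 in itertools.product(range(k), repeat=n):
        labels0 = np.array(labels0)
        w = 0.0
        for j in set(labels0.tolist()):
            pts = X[labels0 == j]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    return float(best)
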