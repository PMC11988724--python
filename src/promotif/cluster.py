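"""Cluster-number diagnostics and bootstrap stability for the feature matrix.

The workflow standardizes the six per-gene variables, checks cluster
tendency by VAT reordering of the distance matrix, reduces to principal
components for display, runs k-means over a range of K, and selects K by
majority vote over three criteria: the elbow of the within-cluster
sum-of-squares curve, the average silhouette width, and the gap statistic
with the one-standard-error rule. Cluster robustness is quantified by
nonparametric bootstrap Jaccard stability with the conventional recovery
(> 0.75) and dissolution (< 0.5) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as _SKPCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler


@dataclass
class StandardizedMatrix:
    values: np.ndarray
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray

    def inverse(self) -> np.ndarray:
        return self.values * self.sds + self.means


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (p, n_components), orthonormal columns
    variance_fraction: np.ndarray


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    wss: float
    n_iter: int
    seed: int


@dataclass
class KSelectionReport:
    ks: list[int]
    wss: dict[int, float]
    silhouette: dict[int, float]
    gap: dict[int, float]
    gap_se: dict[int, float]
    votes: dict[str, int]  # criterion -> chosen K
    chosen_k: int
    rule: str


@dataclass
class StabilityReport:
    k: int
    B: int
    mean_jaccard: np.ndarray  # per original cluster
    recovery_rate: np.ndarray  # fraction of resamples with Jaccard > 0.75
    dissolution_rate: np.ndarray  # fraction with Jaccard < 0.5


def standardize(X: pd.DataFrame | np.ndarray) -> StandardizedMatrix:
    """Column-wise z-scores; constant columns are rejected by name."""
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        values = X.to_numpy(float)
    else:
        values = np.asarray(X, float)
        cols = [f"x{i}" for i in range(values.shape[1])]
    sds = values.std(axis=0, ddof=0)
    bad = [cols[i] for i in np.flatnonzero(sds == 0)]
    if bad:
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    scaler = StandardScaler().fit(values)
    return StandardizedMatrix(
        values=scaler.transform(values),
        columns=cols,
        means=scaler.mean_,
        sds=np.sqrt(scaler.var_),
    )


def vat_order(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Visual Assessment of cluster Tendency ordering of a dissimilarity matrix.

    Prim-style minimum-spanning-tree traversal, seeded at the row that
    contains the maximum dissimilarity; returns the permutation and the
    reordered matrix.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    if n < 2 or D.shape != (n, n):
        raise ValueError("need a square dissimilarity matrix with n >= 2")
    order = [int(np.unravel_index(np.argmax(D), D.shape)[0])]
    remaining = set(range(n)) - set(order)
    while remaining:
        rem = sorted(remaining)
        sub = D[np.ix_(order, rem)]
        j = rem[int(np.unravel_index(np.argmin(sub), sub.shape)[1])]
        order.append(j)
        remaining.discard(j)
    perm = np.array(order)
    return perm, D[np.ix_(perm, perm)]


def pca(X: StandardizedMatrix | np.ndarray, n_components: int | None = None) -> PCAResult:
    """Principal components by SVD with a deterministic sign convention
    (the largest-magnitude loading of each component is positive)."""
    values = X.values if isinstance(X, StandardizedMatrix) else np.asarray(X, float)
    n, p = values.shape
    k = min(n, p) if n_components is None else n_components
    if not 1 <= k <= min(n, p):
        raise ValueError("n_components must lie in [1, min(n, p)]")
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(values)
    loadings = model.components_.T
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total_var = values.var(axis=0, ddof=1).sum()
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=model.explained_variance_ / total_var,
    )


def _wss(values: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float(((values - centroids[labels]) ** 2).sum())


def kmeans(
    X: StandardizedMatrix | np.ndarray,
    k: int,
    restarts: int = 25,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> KMeansResult:
    """k-means++ Lloyd clustering, best of ``restarts`` by within-cluster SS."""
    values = X.values if isinstance(X, StandardizedMatrix) else np.asarray(X, float)
    n = values.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must lie in [1, n]")
    if init is not None:
        km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed).fit(values)
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                    random_state=seed).fit(values)
    labels = km.labels_
    # repair any empty cluster by reseeding from the farthest point
    for c in range(k):
        if not (labels == c).any():
            far = int(np.argmax(((values - km.cluster_centers_[labels]) ** 2).sum(1)))
            labels[far] = c
    centroids = np.vstack([values[labels == c].mean(axis=0) for c in range(k)])
    return KMeansResult(labels=labels, centroids=centroids,
                        wss=_wss(values, labels, centroids),
                        n_iter=int(km.n_iter_), seed=seed)


def _wss_curve(values: np.ndarray, ks: list[int], restarts: int,
               seed: int) -> tuple[dict[int, float], dict[int, KMeansResult]]:
    """Best-of-restarts WSS per K, additionally warm-starting K+1 from the
    K solution plus the farthest point so the curve is non-increasing."""
    wss: dict[int, float] = {}
    fits: dict[int, KMeansResult] = {}
    prev: KMeansResult | None = None
    for k in ks:
        best = kmeans(values, k, restarts=restarts, seed=seed)
        if prev is not None and prev.centroids.shape[0] == k - 1:
            far = int(np.argmax(
                ((values - prev.centroids[prev.labels]) ** 2).sum(axis=1)))
            warm_init = np.vstack([prev.centroids, values[far]])
            warm = kmeans(values, k, seed=seed, init=warm_init)
            if warm.wss < best.wss:
                best = warm
        wss[k] = best.wss
        fits[k] = best
        prev = best
    return wss, fits


def select_k(
    X: StandardizedMatrix | np.ndarray,
    kmax: int = 7,
    B_gap: int = 50,
    restarts: int = 25,
    seed: int = 0,
) -> KSelectionReport:
    """Choose K by majority vote of elbow, silhouette and gap statistic.

    The elbow is the K maximizing the second difference of the WSS curve;
    the silhouette vote is the K with maximal average silhouette width;
    the gap vote follows the one-standard-error rule (smallest K with
    gap(K) >= gap(K+1) - se(K+1)) against B_gap uniform reference sets
    drawn over the data's bounding box. Vote ties resolve toward smaller K.
    """
    if kmax < 2:
        raise ValueError("kmax must be at least 2")
    values = X.values if isinstance(X, StandardizedMatrix) else np.asarray(X, float)
    ks = list(range(1, kmax + 1))
    wss, fits = _wss_curve(values, ks, restarts, seed)

    sil = {
        k: float(silhouette_score(values, fits[k].labels))
        for k in ks if k >= 2 and len(np.unique(fits[k].labels)) > 1
    }
    sil_k = min((k for k in sil if sil[k] == max(sil.values())), default=2)

    w = np.array([wss[k] for k in ks])
    if len(ks) >= 3:
        second_diff = w[:-2] - 2 * w[1:-1] + w[2:]  # at ks[1..kmax-1]
        elbow_k = ks[1 + int(np.argmax(second_diff))]
    else:
        elbow_k = ks[-1]

    rng = np.random.default_rng(seed + 1)
    lo, hi = values.min(axis=0), values.max(axis=0)
    log_w = {k: np.log(wss[k]) if wss[k] > 0 else -np.inf for k in ks}
    ref_log_w = np.empty((B_gap, len(ks)))
    for b in range(B_gap):
        ref = rng.uniform(lo, hi, size=values.shape)
        ref_wss, _ = _wss_curve(ref, ks, restarts=3, seed=seed + 2 + b)
        ref_log_w[b] = [np.log(ref_wss[k]) for k in ks]
    gap = {k: float(ref_log_w[:, i].mean() - log_w[k]) for i, k in enumerate(ks)}
    se = {
        k: float(ref_log_w[:, i].std(ddof=0) * np.sqrt(1 + 1 / B_gap))
        for i, k in enumerate(ks)
    }
    gap_k = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - se[ks[i + 1]]:
            gap_k = k
            break

    votes = {"elbow": elbow_k, "silhouette": sil_k, "gap": gap_k}
    counts: dict[int, int] = {}
    for v in votes.values():
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    chosen = min(k for k, c in counts.items() if c == top)
    rule = "majority" if top > 1 else "tie->smallest"
    return KSelectionReport(ks=ks, wss=wss, silhouette=sil, gap=gap, gap_se=se,
                            votes=votes, chosen_k=chosen, rule=rule)


def _jaccard(a: set[int], b: set[int]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def bootstrap_stability(
    X: StandardizedMatrix | np.ndarray,
    k: int,
    B: int = 100,
    restarts: int = 10,
    seed: int = 0,
) -> StabilityReport:
    """Bootstrap Jaccard stability of the k-means partition.

    Each of B nonparametric resamples is reclustered; every original
    cluster is matched to the resample cluster maximizing the Jaccard
    index over the retained (resampled) points. Recovery counts Jaccard
    > 0.75, dissolution Jaccard < 0.5, following clusterboot conventions.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    values = X.values if isinstance(X, StandardizedMatrix) else np.asarray(X, float)
    n = values.shape[0]
    base = kmeans(values, k, restarts=restarts, seed=seed)
    orig = [set(np.flatnonzero(base.labels == c)) for c in range(k)]
    rng = np.random.default_rng(seed + 17)
    jacc = np.zeros((B, k))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        retained = set(idx.tolist())
        fit = kmeans(values[idx], k, restarts=restarts, seed=seed + 100 + b)
        boot_clusters = [
            set(np.unique(idx[fit.labels == c]).tolist()) for c in range(k)
        ]
        for c in range(k):
            kept = orig[c] & retained
            jacc[b, c] = max((_jaccard(kept, bc) for bc in boot_clusters),
                             default=0.0)
    return StabilityReport(
        k=k,
        B=B,
        mean_jaccard=jacc.mean(axis=0),
        recovery_rate=(jacc > 0.75).mean(axis=0),
        dissolution_rate=(jacc < 0.5).mean(axis=0),
    )
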