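"""Monti-style consensus clustering with CDF/delta-area k selection.

For each candidate k, samples are repeatedly subsampled (H draws of a
proportion p_item without replacement), the base clusterer is run on each
draw, and the consensus matrix M_k(i, j) records how often i and j
co-cluster among the draws that contain both. The empirical CDF of the
upper-triangle consensus entries summarises stability: its area A(k) grows
as the matrix polarises towards {0, 1}, and the relative delta-area
Δ(k) = (A(k) - A(k-1)) / A(k-1) (with Δ(2) = A(2)) flattens once k exceeds
the true structure. k is chosen as the largest k whose Δ(k) clears a
threshold (default 0.1), falling back to the silhouette maximiser.

Base clusterers: k-means (10 restarts) or average-linkage hierarchical
clustering on 1 - Pearson correlation. Features are expected already
scaled by the caller where appropriate (:func:`run_consensus` z-scores
per feature before clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .core_io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus_matrices: dict[int, np.ndarray]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    silhouette: dict[int, float]
    chosen_k: int
    labels: np.ndarray  # cluster assignment (1..chosen_k) for chosen_k
    labels_per_k: dict[int, np.ndarray] = field(default_factory=dict)


def _base_cluster(X: np.ndarray, k: int, method: str, seed: int) -> np.ndarray:
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(X)
    if method == "hclust_pearson":
        corr = np.corrcoef(X)
        corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
        return hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    raise ValidationError(f"unknown base_method {method!r}")


def consensus_matrix(
    X: np.ndarray,
    k: int,
    H: int = 500,
    p_item: float = 0.8,
    base_method: str = "hclust_pearson",
    seed: int = 0,
) -> np.ndarray:
    """Co-clustering frequency matrix over H subsampled clusterings.

    Entries for pairs never drawn together are set to 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k < n:
        raise ValidationError(f"need 2 <= k < n_samples, got k={k}, n={n}")
    if H < 1 or not 0 < p_item <= 1:
        raise ValidationError("need H >= 1 and 0 < p_item <= 1")
    n_sub = max(k, int(round(p_item * n)))

    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for h in range(H):
        idx = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        lab = _base_cluster(X[idx], k, base_method, seed=int(rng.integers(2**31)))
        co = (lab[:, None] == lab[None, :]).astype(float)
        sampled[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += co
    never = sampled == 0
    if never[np.triu_indices(n, k=1)].any():
        logger.warning(
            "%d sample pairs were never co-subsampled; their consensus is 0",
            int(never[np.triu_indices(n, k=1)].sum()),
        )
    with np.errstate(invalid="ignore"):
        M = np.where(never, 0.0, together / np.where(never, 1.0, sampled))
    np.fill_diagonal(M, 1.0)
    return (M + M.T) / 2.0


def cdf_and_delta_area(
    consensus_matrices: dict[int, np.ndarray],
) -> tuple[dict[int, float], dict[int, float]]:
    """Area under the consensus CDF per k, and its relative change.

    A(k) is the exact area on [0, 1] under the (right-continuous)
    empirical CDF of the upper-triangle entries of M_k: a perfectly
    binary matrix with a fraction q of zero entries gives A = q, and an
    all-ones matrix gives A = 0. Δ(2) = A(2);
    Δ(k) = (A(k) - A(k-1)) / A(k-1) for k > 2.
    """
    ks = sorted(consensus_matrices)
    if len(ks) < 2:
        raise ValidationError("need consensus matrices for at least two k values")
    areas: dict[int, float] = {}
    for k in ks:
        M = np.asarray(consensus_matrices[k], dtype=float)
        entries = M[np.triu_indices(M.shape[0], k=1)]
        if entries.size == 0:
            raise ValidationError("consensus matrix has no off-diagonal entries")
        if entries.min() < -1e-12 or entries.max() > 1 + 1e-12:
            raise ValidationError(f"consensus entries outside [0, 1] at k={k}")
        xs = np.unique(np.clip(entries, 0.0, 1.0))
        cdf = np.searchsorted(np.sort(entries), xs, side="right") / entries.size
        # exact integral of the step CDF: each plateau F(x_i) spans [x_i, x_{i+1})
        widths = np.diff(np.r_[xs, 1.0])
        areas[k] = float(np.sum(cdf * widths))
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else np.inf
    return areas, deltas


def select_k(
    cdf_area: dict[int, float],
    delta_area: dict[int, float],
    silhouette: dict[int, float],
    k_range: list[int],
    delta_threshold: float = 0.1,
) -> int:
    """Largest k with Δ(k) >= threshold; fallback: silhouette maximiser."""
    ks = sorted(k_range)
    if not ks:
        raise ValidationError("empty k_range")
    passing = [k for k in ks if delta_area.get(k, -np.inf) >= delta_threshold]
    if passing:
        return max(passing)
    return max(ks, key=lambda k: (silhouette.get(k, -np.inf), -k))


def assign_clusters(M: np.ndarray, k: int) -> np.ndarray:
    """Cut an average-linkage tree on distance 1 - M into k clusters.

    Labels are 1..k, renumbered by decreasing cluster size (ties broken by
    smallest member index).
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if not 2 <= k < n:
        raise ValidationError(f"need 2 <= k < n, got k={k}, n={n}")
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.asarray([remap[c] for c in raw])


def silhouette_score(labels: np.ndarray, distances: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) over samples.

    Samples in singleton clusters, and samples with a = b = 0, contribute 0.
    """
    labels = np.asarray(labels)
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValidationError("silhouette needs at least two clusters")
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return float(s.mean())


def run_consensus(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int = 6,
    H: int = 500,
    p_item: float = 0.8,
    base_method: str = "hclust_pearson",
    delta_threshold: float = 0.1,
    seed: int = 0,
) -> ConsensusResult:
    """Full consensus-clustering run over a k range.

    Features (columns of X) are z-scored before clustering; constant
    features are left at 0. Per-k silhouettes are computed on the
    consensus-derived distance 1 - M_k with that k's own labels.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Xz = (X - mu) / np.where(sd == 0, 1.0, sd)

    k_range = list(range(k_min, k_max + 1))
    matrices: dict[int, np.ndarray] = {}
    sils: dict[int, float] = {}
    labels_per_k: dict[int, np.ndarray] = {}
    for k in k_range:
        M = consensus_matrix(Xz, k, H=H, p_item=p_item, base_method=base_method,
                             seed=seed + 7919 * k)
        matrices[k] = M
        lab = assign_clusters(M, k)
        labels_per_k[k] = lab
        dist = 1.0 - M
        np.fill_diagonal(dist, 0.0)
        sils[k] = silhouette_score(lab, dist)
    areas, deltas = cdf_and_delta_area(matrices)
    chosen = select_k(areas, deltas, sils, k_range, delta_threshold)
    return ConsensusResult(
        k_range=k_range,
        consensus_matrices=matrices,
        cdf_area=areas,
        delta_area=deltas,
        silhouette=sils,
        chosen_k=chosen,
        labels=labels_per_k[chosen],
        labels_per_k=labels_per_k,
    )
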