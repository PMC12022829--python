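"""Waveform-shape clustering of windowed KAM curves.

Each trial's 100 ms window is reduced to the sign of its first differences
(encoding shape, discarding magnitude), pairwise Euclidean distances between
the sign vectors are clustered by Ward.D2 agglomeration, the partition quality
is scored with the Hubert-Levin c-index, and each cluster's mean waveform is
classified as containing an early peak or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from kamrisk.config import ClusteringConfig


class UndefinedIndexError(ValueError):
    """The c-index is undefined (single cluster, no within pairs, or constant distances)."""


def sign_diff_transform(window: np.ndarray) -> np.ndarray:
    """Sign of the differentiated curve: element i = sign(w[i+1] - w[i]).

    sign(0) = 0.  Length = window length - 1 (39 for a 40-sample window).
    Invariant to positive affine rescaling of the waveform.  Accepts a single
    window or a matrix of windows (last axis = time).
    """
    window = np.asarray(window)
    if window.shape[-1] < 2:
        raise ValueError("window must have at least 2 samples")
    return np.sign(np.diff(window, axis=-1))


def pairwise_distances(sign_vectors: np.ndarray) -> np.ndarray:
    """Symmetric matrix of Euclidean distances between sign vectors."""
    sv = np.asarray(sign_vectors, dtype=float)
    if sv.ndim != 2:
        raise ValueError("expected a 2-D array of equal-length sign vectors")
    return squareform(pdist(sv, metric="euclidean"))


def ward_linkage(D: np.ndarray) -> np.ndarray:
    """Ward.D2 linkage (Murtagh-Legendre) from a square distance matrix.

    Uses the Lance-Williams recurrence on squared distances with square-rooted
    merge heights, i.e. the criterion of R's ``hclust(method="ward.D2")``.
    """
    condensed = squareform(np.asarray(D, dtype=float), checks=False)
    return linkage(condensed, method="ward")


def ward_d2_cluster(D: np.ndarray, k: int, Z: np.ndarray | None = None):
    """Cut the Ward.D2 dendrogram at k clusters.

    Returns ``(labels, merge_history)`` where labels are 1..k and the merge
    history is the (n-1, 4) linkage record (merged ids, height, cluster size).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    if Z is None:
        Z = ward_linkage(D)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def c_index(D: np.ndarray, labels: np.ndarray) -> float:
    """Hubert-Levin c-index of a partition given the pairwise distance matrix.

    C = (S_w - S_min) / (S_max - S_min), where S_w is the sum of within-cluster
    pairwise distances over the N_w within-cluster pairs and S_min / S_max are
    the sums of the N_w smallest / largest distances in the whole matrix.
    0 means within-cluster pairs are exactly the globally closest pairs.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if len(np.unique(labels)) < 2:
        raise UndefinedIndexError("c-index needs at least two clusters")
    iu, ju = np.triu_indices(n, k=1)
    d = D[iu, ju]
    within = labels[iu] == labels[ju]
    n_w = int(within.sum())
    if n_w == 0:
        raise UndefinedIndexError("no within-cluster pairs")
    s_w = float(d[within].sum())
    part = np.partition(d, (n_w - 1, len(d) - n_w))
    s_min = float(part[:n_w].sum())
    s_max = float(part[len(d) - n_w :].sum())
    if s_max == s_min:
        raise UndefinedIndexError("all pairwise distances identical")
    return (s_w - s_min) / (s_max - s_min)


def select_k(
    D: np.ndarray, k_range: tuple[int, int] = (2, 10), Z: np.ndarray | None = None
) -> tuple[int, dict[int, float]]:
    """Choose k by c-index minimisation over ``k_range`` (ties -> smallest k).

    Returns the selected k and the per-k c-index values actually evaluated.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    lo = max(2, k_range[0])
    hi = min(n - 1, k_range[1])
    if hi < lo:
        raise ValueError("no admissible k in range")
    if Z is None:
        Z = ward_linkage(D)
    scores: dict[int, float] = {}
    for k in range(lo, hi + 1):
        labels, _ = ward_d2_cluster(D, k, Z=Z)
        if len(np.unique(labels)) != k:  # dendrogram ties can skip a k
            continue
        try:
            scores[k] = c_index(D, labels)
        except UndefinedIndexError:
            continue
    if not scores:
        raise UndefinedIndexError("c-index undefined for every k in range")
    # smallest k whose score ties the minimum (tolerance absorbs float dust)
    c_min = min(scores.values())
    best = min(k for k, v in scores.items() if v <= c_min + 1e-9)
    return best, scores


def classify_early_peak(
    cluster_mean: np.ndarray,
    min_drop_frac: float = 0.10,
    min_drop_abs: float = 0.02,
) -> bool:
    """Early-peak rule for a cluster's mean waveform over the analysis window.

    TRUE iff the global maximum is positive, is attained at an interior sample,
    and the curve declines from the peak to the window end by at least
    max(min_drop_frac * peak, min_drop_abs) N.m/kg.
    """
    w = np.asarray(cluster_mean, dtype=float)
    peak_idx = int(np.argmax(w))
    peak = w[peak_idx]
    if peak <= 0.0:
        return False
    if peak_idx == 0 or peak_idx == len(w) - 1:
        return False
    drop = peak - w[-1]
    return drop >= max(min_drop_frac * peak, min_drop_abs)


@dataclass
class ClusterSolution:
    """Partition of trials by waveform shape plus per-cluster summaries."""

    labels: np.ndarray  # 1..k per trial
    k: int
    merge_history: np.ndarray  # scipy linkage record
    c_index: float
    cluster_means: np.ndarray  # (k, window_len) mean filtered KAM
    early_peak_flags: np.ndarray  # (k,) booleans
    c_index_by_k: dict[int, float] | None = None

    @property
    def early_peak_trial_mask(self) -> np.ndarray:
        return self.early_peak_flags[self.labels - 1]


def cluster_windows(
    windows: np.ndarray, config: ClusteringConfig | None = None
) -> ClusterSolution:
    """Full shape-clustering stage: transform, distances, Ward.D2, c-index, flags."""
    cfg = config or ClusteringConfig()
    windows = np.asarray(windows, dtype=float)
    signs = sign_diff_transform(windows)
    D = pairwise_distances(signs)
    Z = ward_linkage(D)
    scores: dict[int, float] | None = None
    if cfg.k is not None:
        k = cfg.k
    else:
        k, scores = select_k(D, (cfg.k_min, cfg.k_max), Z=Z)
    labels, Z = ward_d2_cluster(D, k, Z=Z)
    ci = c_index(D, labels)
    means = np.stack([windows[labels == c].mean(axis=0) for c in range(1, k + 1)])
    flags = np.array(
        [
            classify_early_peak(means[c], cfg.min_peak_drop_frac, cfg.min_peak_drop_abs)
            for c in range(k)
        ]
    )
    return ClusterSolution(
        labels=labels,
        k=k,
        merge_history=Z,
        c_index=ci,
        cluster_means=means,
        early_peak_flags=flags,
        c_index_by_k=scores,
    )
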