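"""One-mode k-means baseline and silhouette-based choice of k.

The comparison arm: cluster examinees on all P features at once (raw,
unstandardized scale, matching the pipeline's no-standardization
preprocessing), pick k by the average silhouette width, and adapt the
partition to biclusters via :func:`biclog.metrics.partition_to_biclusters`
when comparing against the biclustering algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .data import FeatureMatrix

__all__ = ["ClusterSolution", "run_kmeans", "silhouette_selection"]


def _values(A) -> np.ndarray:
    return A.values if isinstance(A, FeatureMatrix) else np.asarray(A, dtype=float)


@dataclass
class ClusterSolution:
    labels: np.ndarray  # 0-based cluster id per examinee
    k: int
    inertia: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(self.labels.tolist())
        if present != set(range(self.k)):
            raise ValueError("labels must use every cluster id in 0..k-1")


def run_kmeans(
    A: FeatureMatrix | np.ndarray, k: int, seed: int = 0, restarts: int = 10
) -> ClusterSolution:
    """Best-of-``restarts`` k-means on the raw feature values."""
    X = _values(A)
    if not 1 <= k <= X.shape[0]:
        raise ValueError("k must be between 1 and the number of examinees")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    # relabel so ids are contiguous even if sklearn dropped a cluster
    uniq = np.unique(km.labels_)
    remap = {int(u): i for i, u in enumerate(uniq)}
    labels = np.asarray([remap[int(l)] for l in km.labels_])
    return ClusterSolution(labels=labels, k=len(uniq), inertia=float(km.inertia_))


def silhouette_selection(
    A: FeatureMatrix | np.ndarray,
    k_max: int = 30,
    seed: int = 0,
    restarts: int = 10,
    subsample_above: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average silhouette width for k = 2..k_max and the chosen k.

    Returns ``(ks, widths, chosen_k)`` with ``chosen_k`` the argmax
    (smallest k on ties).  Silhouette is computed on all N points unless
    ``subsample_above`` is set and exceeded.
    """
    X = _values(A)
    n = X.shape[0]
    if n < 3:
        raise ValueError("silhouette selection needs at least 3 examinees")
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    k_max = min(k_max, n - 1)

    rng = np.random.default_rng(seed)
    if subsample_above is not None and n > subsample_above:
        idx = rng.choice(n, size=subsample_above, replace=False)
    else:
        idx = np.arange(n)

    ks = np.arange(2, k_max + 1)
    widths = np.empty(ks.shape[0])
    for i, k in enumerate(ks):
        sol = run_kmeans(X, int(k), seed=seed, restarts=restarts)
        if len(set(sol.labels[idx].tolist())) < 2:
            widths[i] = -1.0
        else:
            widths[i] = float(silhouette_score(X[idx], sol.labels[idx]))
    chosen = int(ks[int(np.argmax(widths))])  # argmax returns the first (smallest k) tie
    return ks, widths, chosen
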