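"""Density-Based Clustering Validation (DBCV) index.

Scores a density partition in [-1, 1] by comparing, for each cluster,
its internal density sparseness (the widest edge of the mutual-
reachability minimum spanning tree) against its density separation
from the other clusters (the narrowest mutual-reachability gap).
Noise points contribute zero weight.  All points of a cluster are used
(rather than only the MST-internal nodes), a common simplification.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist


def _all_points_core_distance(dist: np.ndarray, dim: int) -> np.ndarray:
    """Inverse-power mean of distances to all other cluster members."""
    n = dist.shape[0]
    core = np.empty(n)
    for i in range(n):
        d = np.delete(dist[i], i)
        d = d[d > 0]
        if len(d) == 0:
            core[i] = 0.0
            continue
        core[i] = (np.mean((1.0 / d) ** dim)) ** (-1.0 / dim)
    return core


def _mutual_reachability(dist: np.ndarray, core_a: np.ndarray,
                         core_b: np.ndarray) -> np.ndarray:
    return np.maximum(dist, np.maximum.outer(core_a, core_b))


def dbcv_score(X: np.ndarray, labels: np.ndarray) -> float:
    """DBCV validity of a labelled partition (noise = -1).

    Returns 0.0 when fewer than two clusters of size >= 2 exist (no
    density structure to validate).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, dim = X.shape
    clusters = [c for c in np.unique(labels) if c != -1]
    clusters = [c for c in clusters if np.sum(labels == c) >= 2]
    if len(clusters) < 2:
        return 0.0

    cores: dict[int, np.ndarray] = {}
    sparseness: dict[int, float] = {}
    members: dict[int, np.ndarray] = {}
    for c in clusters:
        idx = np.where(labels == c)[0]
        members[c] = idx
        d = cdist(X[idx], X[idx])
        core = _all_points_core_distance(d, dim)
        cores[c] = core
        mr = _mutual_reachability(d, core, core)
        mst = minimum_spanning_tree(mr).toarray()
        sparseness[c] = float(mst.max())

    separation: dict[int, float] = {}
    for c in clusters:
        best = np.inf
        for o in clusters:
            if o == c:
                continue
            d = cdist(X[members[c]], X[members[o]])
            mr = _mutual_reachability(d, cores[c], cores[o])
            best = min(best, float(mr.min()))
        separation[c] = best

    total = 0.0
    for c in clusters:
        sep, spa = separation[c], sparseness[c]
        denom = max(sep, spa)
        v = 0.0 if denom == 0 else (sep - spa) / denom
        total += len(members[c]) * v
    return total / n
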