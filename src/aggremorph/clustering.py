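"""Density-based clustering of localizations into aggregates.

A from-scratch DBSCAN matched to the conventions the original analysis
relied on: a point is *core* iff its closed eps-neighbourhood (the point
itself included) holds at least ``min_pts`` points; clusters are the
connected components of core points under mutual eps-reachability; border
points (non-core points within eps of a core point) join the cluster of
their first core neighbour in ascending row order, which makes the output
deterministic and independent of traversal order.  Everything else is
noise, labelled -1.  Cluster ids are assigned in order of each cluster's
first member row so repeated runs produce identical label files.

A k-d tree serves as the spatial index; the contract is purely about the
output partition, which tests pin against an O(n^2) reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = ["ClusterLabeling", "dbscan", "dbscan_brute_force"]

NOISE = -1


@dataclass
class ClusterLabeling:
    """Per-point cluster assignment with a noise sentinel.

    ``labels[i]`` is -1 for noise or the cluster id in [0, n_clusters);
    ``core_flags[i]`` marks core points (never noise).
    """

    labels: np.ndarray
    n_clusters: int
    core_flags: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.core_flags = np.asarray(self.core_flags, dtype=bool)
        if self.labels.shape != self.core_flags.shape:
            raise ValueError("labels and core_flags must have equal length")
        if np.any(self.labels[self.core_flags] == NOISE):
            raise ValueError("a core point can never be labelled noise")
        non_noise = self.labels[self.labels != NOISE]
        distinct = np.unique(non_noise).size
        if distinct != self.n_clusters:
            raise ValueError("n_clusters does not match the distinct labels")
        if non_noise.size and (non_noise.min() < 0 or non_noise.max() >= self.n_clusters):
            raise ValueError("cluster labels must lie in [0, n_clusters)")


def _canonical_relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber clusters in order of their first member row."""
    out = np.full(labels.shape, NOISE, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out, len(mapping)


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> ClusterLabeling:
    """Cluster 2D points (nm) with detection radius ``eps`` and threshold ``min_pts``.

    Matches the study's clustering settings when called with eps 75 nm /
    min_pts 9 (thioflavin-X) or eps 200 nm / min_pts 10 (aptamer-PAINT).
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return ClusterLabeling(np.empty(0, np.int64), 0, np.empty(0, bool))
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = points.shape[0]

    tree = cKDTree(points)
    counts = tree.query_ball_point(points, eps, return_length=True)
    core = counts >= min_pts
    labels = np.full(n, NOISE, dtype=np.int64)

    core_idx = np.nonzero(core)[0]
    if core_idx.size:
        core_tree = cKDTree(points[core_idx])
        pairs = core_tree.query_pairs(eps, output_type="ndarray")
        graph = sparse.csr_matrix(
            (np.ones(pairs.shape[0], dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
            shape=(core_idx.size, core_idx.size),
        )
        _, comp = sparse.csgraph.connected_components(graph, directed=False)
        labels[core_idx] = comp

        # border points: first core neighbour in ascending row order wins
        border_idx = np.nonzero(~core)[0]
        if border_idx.size:
            neigh = core_tree.query_ball_point(points[border_idx], eps)
            for b, nb in zip(border_idx, neigh):
                if nb:
                    first_core = core_idx[min(nb)]  # core_idx ascending
                    labels[b] = labels[first_core]

    labels, k = _canonical_relabel(labels)
    return ClusterLabeling(labels, k, core)


def dbscan_brute_force(points: np.ndarray, eps: float, min_pts: int) -> ClusterLabeling:
    """O(n^2) reference implementation used as the clustering oracle.

    Builds the full distance matrix, derives core points, takes connected
    components of the core-core reachability graph by breadth-first search,
    and attaches border points with the same first-core-neighbour rule.
    Output must match :func:`dbscan` exactly.
    """
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return ClusterLabeling(np.empty(0, np.int64), 0, np.empty(0, bool))
    n = points.shape[0]
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps * eps
    core = adj.sum(axis=1) >= min_pts
    labels = np.full(n, NOISE, dtype=np.int64)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for nb in np.nonzero(adj[j] & core)[0]:
                if labels[nb] == NOISE:
                    labels[nb] = cluster
                    stack.append(nb)
        cluster += 1
    for i in range(n):
        if core[i] or labels[i] != NOISE:
            continue
        nbs = np.nonzero(adj[i] & core)[0]
        if nbs.size:
            labels[i] = labels[nbs[0]]
    labels, k = _canonical_relabel(labels)
    return ClusterLabeling(labels, k, core)
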