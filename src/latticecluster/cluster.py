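"""Metric-space clustering: dendrogram, slicing, k-medoids, centroid
designation, and empirical (Hausdorff) dimension estimation.

All operations work on a precomputed :class:`~latticecluster.metrics.DistanceMatrix`;
no averaging of items is ever performed (lattices do not form a linear
space), so every representative is a medoid.  Tie-breaking is always by
lowest input index, making every operation deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy as _hier

from .metrics import DistanceMatrix

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "DimensionEstimate",
    "hierarchical",
    "slice_dendrogram",
    "seeds_from_slice",
    "kmedoids",
    "designate_centroid",
    "estimate_dimension",
]

LINKAGES = ("single", "average", "complete")


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` holds (cluster_i, cluster_j, height, size) records in the
    scipy linkage convention: leaves are 0..n-1 and merge k creates
    cluster n+k.
    """

    linkage_matrix: np.ndarray
    labels: list[str]

    def __post_init__(self):
        z = np.asarray(self.linkage_matrix, dtype=float)
        if z.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows of 4 columns")
        heights = z[:, 2]
        if (np.diff(heights) < -1e-9).any():
            raise ValueError("merge heights must be non-decreasing")
        self.linkage_matrix = z

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(i), int(j), float(h), int(sz)) for i, j, h, sz in self.linkage_matrix]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def largest_gap_level(self, min_gap: float = 0.0) -> float:
        """Cut level in the middle of the largest gap between consecutive
        merge heights.  If there is no gap larger than ``min_gap`` (or
        fewer than two merges), returns a level above the top merge, i.e.
        a single cluster: a merge sequence without a pronounced gap gives
        no evidence for more than one cluster."""
        h = np.sort(self.heights)
        gaps = np.diff(h)
        if len(gaps) == 0 or gaps.max() <= max(min_gap, 1e-12):
            return float(h[-1]) + 1.0
        k = int(np.argmax(gaps))
        return float((h[k] + h[k + 1]) / 2.0)

    def to_newick(self) -> str:
        """Newick export with branch lengths = merge-height differences."""
        n = self.n_leaves
        node_height = {i: 0.0 for i in range(n)}
        node_repr = {i: _escape_newick(self.labels[i]) for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.merges):
            bi = h - node_height[i]
            bj = h - node_height[j]
            node_repr[n + k] = f"({node_repr[i]}:{bi:.6f},{node_repr[j]}:{bj:.6f})"
            node_height[n + k] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node_repr[root] + ";"


def _escape_newick(label: str) -> str:
    if any(ch in label for ch in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class ClusterAssignment:
    """Flat clustering: per-item labels, per-cluster medoids, objective."""

    labels: np.ndarray            # per-item cluster index, 0..k-1
    medoids: list[int]            # per-cluster representative item index
    objective: float              # sum over items of distance to own medoid
    item_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        k = len(self.medoids)
        if k and set(self.labels) != set(range(k)):
            raise ValueError("cluster labels must be 0..k-1 with no empty cluster")
        for ci, m in enumerate(self.medoids):
            if self.labels[m] != ci:
                raise ValueError("each medoid must belong to its own cluster")
        if not self.item_labels:
            self.item_labels = [str(i) for i in range(len(self.labels))]

    @property
    def k(self) -> int:
        return len(self.medoids)

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]

    def to_tsv(self) -> str:
        medoid_set = set(self.medoids)
        lines = ["id\tcluster\tis_medoid"]
        for i, lab in enumerate(self.item_labels):
            lines.append(f"{lab}\t{self.labels[i]}\t{1 if i in medoid_set else 0}")
        return "\n".join(lines) + "\n"


@dataclass
class DimensionEstimate:
    """Log-log ball-counting dimension estimate."""

    dimension: float
    r_values: np.ndarray
    counts: np.ndarray
    fit_range: tuple[int, int]

    def __post_init__(self):
        if self.dimension < -1e-9:
            raise ValueError("dimension must be non-negative")
        if (np.diff(self.counts) < 0).any():
            raise ValueError("ball counts must be non-decreasing in radius")


# ---------------------------------------------------------------------------


def hierarchical(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix; returns the merge tree."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if dm.n < 2:
        raise ValueError("hierarchical clustering needs at least 2 items")
    z = _hier.linkage(dm.condensed(), method=linkage)
    z[:, 2] = np.maximum(z[:, 2], 0.0)  # clip tiny negative rounding
    return Dendrogram(z, list(dm.labels))


def _medoid_of(dm: DistanceMatrix, members: np.ndarray) -> int:
    sub = dm.d[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])  # argmin ties -> lowest index


def _assignment_from_labels(dm: DistanceMatrix, raw_labels: np.ndarray) -> ClusterAssignment:
    # relabel clusters by lowest member index for determinism
    order: dict[int, int] = {}
    for i, lab in enumerate(raw_labels):
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in raw_labels])
    medoids = []
    for ci in range(len(order)):
        members = np.nonzero(labels == ci)[0]
        medoids.append(_medoid_of(dm, members))
    objective = float(sum(dm.d[i, medoids[labels[i]]] for i in range(dm.n)))
    return ClusterAssignment(labels, medoids, objective, list(dm.labels))


def slice_dendrogram(dg: Dendrogram, level: float, dm: DistanceMatrix) -> ClusterAssignment:
    """Flat clusters = connected components of merges with height <= level."""
    if level < 0:
        raise ValueError("slice level must be >= 0")
    raw = _hier.fcluster(dg.linkage_matrix, t=level, criterion="distance")
    return _assignment_from_labels(dm, raw)


def seeds_from_slice(dg: Dendrogram, level: float, dm: DistanceMatrix) -> list[int]:
    """Medoids of the slice's clusters, usable as k-medoids seeds."""
    return list(slice_dendrogram(dg, level, dm).medoids)


def kmedoids(
    dm: DistanceMatrix,
    k: int,
    seeds: list[int] | None = None,
    restarts: int = 10,
    rng_seed: int = 0,
) -> ClusterAssignment:
    """k-medoids by alternating assignment / medoid update.

    The first start uses ``seeds`` when given; remaining restarts draw
    distinct random medoids from ``rng_seed``.  An "unfortunately
    chosen" start (empty cluster, or objective worse than the best so
    far) is simply superseded by the best result over all restarts.
    The paper's "k-means" is implemented strictly as k-medoids: cluster
    averages are not meaningful for lattices.
    """
    n = dm.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if seeds is not None:
        seeds = list(seeds)
        if len(seeds) != k or len(set(seeds)) != k:
            raise ValueError("seeds must be k distinct item indices")
    rng = np.random.default_rng(rng_seed)
    starts: list[list[int]] = []
    if seeds is not None:
        starts.append(seeds)
    while len(starts) < max(1, restarts):
        starts.append(sorted(rng.choice(n, size=k, replace=False).tolist()))

    best: ClusterAssignment | None = None
    for start in starts:
        medoids = list(start)
        prev_labels = None
        ok = True
        for _ in range(1000):
            dist_to_medoids = dm.d[:, medoids]
            labels = np.argmin(dist_to_medoids, axis=1)  # ties -> lowest medoid position
            for ci, m in enumerate(medoids):  # a medoid always stays in its own cluster
                labels[m] = ci
            if any((labels == ci).sum() == 0 for ci in range(k)):
                ok = False
                break
            new_medoids = [
                _medoid_of(dm, np.nonzero(labels == ci)[0]) for ci in range(k)
            ]
            if prev_labels is not None and np.array_equal(labels, prev_labels) \
                    and new_medoids == medoids:
                break
            prev_labels = labels
            medoids = new_medoids
        if not ok:
            continue
        assignment = _assignment_from_labels(dm, labels)
        if best is None or assignment.objective < best.objective - 1e-12:
            best = assignment
    if best is None:
        raise RuntimeError("all k-medoids starts produced empty clusters")
    return best


def designate_centroid(dm: DistanceMatrix, n_dim: int, rng_seed: int = 0) -> int:
    """Centroid designation by farthest-point landmarks.

    Draw a random start item, greedily pick ``n_dim`` landmarks each
    maximizing its minimum distance to everything already chosen
    (including the start), then return the item minimizing the sum of
    distances to the landmarks (ties -> lowest index).
    """
    n = dm.n
    if n_dim < 1:
        raise ValueError("n_dim must be >= 1")
    if n_dim >= n:
        raise ValueError("matrix must have at least n_dim + 1 items")
    rng = np.random.default_rng(rng_seed)
    l_start = int(rng.integers(n))
    chosen = [l_start]
    landmarks: list[int] = []
    for _ in range(n_dim):
        min_d = dm.d[:, chosen].min(axis=1)
        min_d[chosen] = -1.0
        nxt = int(np.argmax(min_d))  # argmax ties -> lowest index
        chosen.append(nxt)
        landmarks.append(nxt)
    sums = dm.d[:, landmarks].sum(axis=1)
    return int(np.argmin(sums))


def estimate_dimension(
    dm: DistanceMatrix, center: int, n_radii: int = 20
) -> DimensionEstimate:
    """Empirical dimension: least-squares slope of log(count in ball)
    versus log(radius) on a geometric radius grid between the 5th and
    95th percentile of distances from ``center``; the fit uses radii
    where 3 <= count <= 0.9 n.
    """
    n = dm.n
    if n < 10:
        raise ValueError("dimension estimation needs at least 10 items")
    dists = np.delete(dm.d[center], center)
    lo = float(np.percentile(dists, 5))
    hi = float(np.percentile(dists, 95))
    if hi <= 0:
        # all points coincide: counts are constant in radius, slope 0
        r = np.ones(n_radii)
        counts = np.full(n_radii, n - 1)
        return DimensionEstimate(0.0, r, counts, (0, n_radii))
    lo = max(lo, hi * 1e-6)
    r = np.geomspace(lo, hi, n_radii)
    counts = np.array([(dists <= radius).sum() for radius in r])
    usable = np.nonzero((counts >= 3) & (counts <= 0.9 * n))[0]
    if len(usable) < 3:
        raise ValueError("fewer than 3 usable radii; dimension estimate undefined")
    first, last = int(usable[0]), int(usable[-1]) + 1
    x = np.log(r[first:last])
    y = np.log(counts[first:last])
    if np.ptp(y) <= 1e-12:
        slope = 0.0
    else:
        slope = float(np.polyfit(x, y, 1)[0])
    return DimensionEstimate(max(slope, 0.0), r, counts, (first, last))
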