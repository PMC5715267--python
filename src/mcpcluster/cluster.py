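"""The icc-cluster k-medoid algorithm and a k-means comparison baseline.

icc-cluster ("iterating clustering centers") is a deterministic k-medoid
scheme.  Seeding is farthest-first: the first two centers are the pair of
genes at maximum dissimilarity, and each further center is the non-center
gene maximizing its minimum dissimilarity to all centers chosen so far
(maximin).  The algorithm then alternates nearest-center assignment with a
within-cluster medoid update (the member minimizing the sum of
dissimilarities to all members of its cluster) until the label vector stops
changing.  All ties break toward the lowest gene index, so identical inputs
give identical outputs with no randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .mcp import MEASURES, DissimilarityMatrix, _features, pairwise_dissimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "icc_seed_centers",
    "icc_assign",
    "icc_update_medoid",
    "icc_cluster",
    "kmeans_baseline",
    "subcluster_consistency",
]


@dataclass
class ClusterAssignment:
    """Clustering result: per-gene labels in 1..k plus center gene indices.

    ``medoids[j - 1]`` is the (0-based) gene index of the center of cluster
    ``j``; that gene always carries label ``j``.  ``objective`` is the sum
    over genes of the dissimilarity to their cluster center.  For the
    k-means baseline the "medoid" reported is the member closest to the
    final centroid, and ``extras`` records seeding details.
    """

    labels: np.ndarray
    medoids: np.ndarray
    objective: float
    n_iterations: int
    converged: bool
    k: int
    algorithm: str
    measure: str | None = None
    extras: dict = field(default_factory=dict)

    def members(self, cluster: int) -> np.ndarray:
        """Gene indices belonging to cluster ``cluster`` (1-based)."""
        return np.nonzero(self.labels == cluster)[0]


def _dvalues(D: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    d = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    return d


def icc_seed_centers(D: DissimilarityMatrix | np.ndarray, k: int) -> np.ndarray:
    """Farthest-first (maximin) seeding of k cluster centers.

    The first two centers attain the maximum pairwise dissimilarity; each
    subsequent center maximizes, over non-centers, the minimum dissimilarity
    to all previously chosen centers.  Ties break toward the lowest index
    (lexicographically lowest pair for the first two).
    """
    d = _dvalues(D)
    m = d.shape[0]
    if not 2 <= k <= m:
        raise ValueError(f"k must be in 2..{m}, got {k}")
    # row-major argmax over the strict upper triangle -> lexicographically
    # smallest maximizing pair
    masked = np.where(np.triu(np.ones_like(d, dtype=bool), 1), d, -np.inf)
    i, j = np.unravel_index(np.argmax(masked), d.shape)
    centers = [int(i), int(j)]
    mindist = np.minimum(d[:, i], d[:, j])
    while len(centers) < k:
        cand = mindist.copy()
        cand[centers] = -np.inf
        nxt = int(np.argmax(cand))
        centers.append(nxt)
        mindist = np.minimum(mindist, d[:, nxt])
    return np.asarray(centers, dtype=int)


def icc_assign(D: DissimilarityMatrix | np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Assign each gene to its nearest center; returns labels in 1..k.

    Cluster ``j`` corresponds to ``centers[j - 1]``.  A gene equidistant to
    several centers goes to the center with the lowest gene index; a center
    always belongs to its own cluster.
    """
    d = _dvalues(D)
    centers = np.asarray(centers, dtype=int)
    if len(set(centers.tolist())) != centers.size:
        raise ValueError("centers must be distinct")
    # break distance ties toward the lowest *gene* index, not list position
    order = np.argsort(centers, kind="stable")
    pos = np.argmin(d[:, centers[order]], axis=1)
    labels = order[pos] + 1
    labels[centers] = np.arange(1, centers.size + 1)
    return labels


def icc_update_medoid(D: DissimilarityMatrix | np.ndarray, members: np.ndarray) -> int:
    """Member minimizing the sum of dissimilarities to all cluster members."""
    d = _dvalues(D)
    members = np.asarray(sorted(int(i) for i in np.asarray(members).ravel()), dtype=int)
    if members.size == 0:
        raise ValueError("cannot take the medoid of an empty cluster")
    sums = d[np.ix_(members, members)].sum(axis=1)
    return int(members[int(np.argmin(sums))])


def _objective(d: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(d[np.arange(d.shape[0]), centers[labels - 1]].sum())


def icc_cluster(
    D: DissimilarityMatrix | np.ndarray,
    k: int,
    max_iter: int = 100,
    measure: str | None = None,
) -> ClusterAssignment:
    """Run icc-cluster to a fixed point of the assign/medoid-update loop.

    Deterministic: farthest-first seeding, then alternate nearest-center
    assignment and medoid update until the label vector is unchanged between
    successive iterations (or ``max_iter`` is hit, in which case the
    best-so-far assignment is returned with ``converged=False`` and a
    warning).  The objective (sum of within-cluster dissimilarity to the
    medoid) is non-increasing across iterations; the trace is kept in
    ``extras['objective_trace']``.
    """
    d = _dvalues(D)
    if isinstance(D, DissimilarityMatrix) and measure is None:
        measure = D.measure
    centers = icc_seed_centers(d, k)
    labels = icc_assign(d, centers)
    trace = [_objective(d, labels, centers)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        centers = np.asarray(
            [icc_update_medoid(d, np.nonzero(labels == j)[0]) for j in range(1, k + 1)],
            dtype=int,
        )
        new_labels = icc_assign(d, centers)
        trace.append(_objective(d, new_labels, centers))
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels
    if not converged:
        logger.warning("icc_cluster did not converge within %d iterations", max_iter)
    return ClusterAssignment(
        labels=labels,
        medoids=centers,
        objective=trace[-1],
        n_iterations=n_iter,
        converged=converged,
        k=k,
        algorithm="icc",
        measure=measure,
        extras={"objective_trace": trace},
    )


# ---------------------------------------------------------------------------
# k-means baseline


def _kmeans_distances(F: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    """Distance of every feature row to every centroid row."""
    if metric == "euclidean":
        return ((F[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    # correlation distance 1 - r, with r = 0 for constant vectors by policy
    Fz = F - F.mean(axis=1, keepdims=True)
    Cz = C - C.mean(axis=1, keepdims=True)
    fn = np.linalg.norm(Fz, axis=1)
    cn = np.linalg.norm(Cz, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Fz @ Cz.T) / np.outer(fn, cn)
    r[~np.isfinite(r)] = 0.0
    return 1.0 - np.clip(r, -1.0, 1.0)


def kmeans_baseline(
    E: ExpressionMatrix | np.ndarray,
    k: int,
    measure: str = "pcc-mcp",
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Lloyd-style k-means on the feature vectors a measure implies.

    MCP vectors for the ``*-mcp`` measures, normalized profiles otherwise;
    squared Euclidean distance for ``ed-*`` and ``1 - r`` (Pearson) for
    ``pcc-*``.  Centroids are arithmetic means of members.  Seeding is
    k-means++-style from ``seed``; an emptied cluster is reseeded to the
    point farthest from its assigned centroid.  ``k = 1`` is allowed and
    puts everything in one cluster.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    F = _features(E, measure)
    m = F.shape[0]
    if k > m:
        raise ValueError(f"k={k} exceeds number of genes {m}")
    metric = "euclidean" if measure.startswith("ed") else "correlation"
    rng = np.random.default_rng(seed)

    # k-means++ seeding: next seed drawn with probability proportional to
    # squared distance to the nearest existing seed
    seeds = [int(rng.integers(m))]
    while len(seeds) < k:
        dist = _kmeans_distances(F, F[seeds], metric).min(axis=1)
        w = dist**2
        total = w.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(m), seeds)
            seeds.append(int(rng.choice(remaining)))
            continue
        seeds.append(int(rng.choice(m, p=w / total)))
    C = F[seeds].copy()

    labels = np.zeros(m, dtype=int)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = _kmeans_distances(F, C, metric)
        new_labels = dist.argmin(axis=1) + 1
        reseeded: set[int] = set()
        for j in range(1, k + 1):
            if not np.any(new_labels == j):
                to_centroid = dist[np.arange(m), new_labels - 1].copy()
                if reseeded:
                    to_centroid[list(reseeded)] = -np.inf
                far = int(to_centroid.argmax())
                new_labels[far] = j
                reseeded.add(far)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for j in range(1, k + 1):
            C[j - 1] = F[labels == j].mean(axis=0)
    dist = _kmeans_distances(F, C, metric)
    objective = float(dist[np.arange(m), labels - 1].sum())
    medoids = np.asarray(
        [
            int(np.nonzero(labels == j)[0][dist[labels == j, j - 1].argmin()])
            for j in range(1, k + 1)
        ],
        dtype=int,
    )
    return ClusterAssignment(
        labels=labels,
        medoids=medoids,
        objective=objective,
        n_iterations=n_iter,
        converged=converged,
        k=k,
        algorithm="kmeans",
        measure=measure,
        extras={"seed": seed, "seeding": "kmeans++", "empty_cluster": "farthest-point"},
    )


def subcluster_consistency(
    sub_labels: np.ndarray, super_labels: np.ndarray
) -> pd.DataFrame:
    """Membership overlap between a finer and a coarser clustering.

    For each sub-cluster (larger k) the table reports its size, the
    super-cluster (smaller k) contributing most of its members, and that
    majority fraction in percent ("sensitivity").  Label identities across
    runs are arbitrary, so comparisons use overlap counts only.
    """
    sub_labels = np.asarray(sub_labels)
    super_labels = np.asarray(super_labels)
    if sub_labels.shape != super_labels.shape:
        raise ValueError("label vectors must have equal length")
    rows = []
    for sub in np.unique(sub_labels):
        mask = sub_labels == sub
        total = int(mask.sum())
        values, counts = np.unique(super_labels[mask], return_counts=True)
        top = int(np.argmax(counts))
        rows.append(
            {
                "subcluster": sub,
                "total": total,
                "majority_supercluster": values[top],
                "majority_count": int(counts[top]),
                "sensitivity_pct": 100.0 * counts[top] / total,
            }
        )
    return pd.DataFrame(rows)
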