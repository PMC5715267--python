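"""PCA truncation of MCP vectors, t-SNE maps, silhouette-based map selection.

MCP vectors live in n^2 dimensions but have rank at most n - 1 after
centering, so their PCA scores ("KC-data") compress them losslessly at
k = n - 1 and progressively at smaller k.  A 2D t-SNE embedding is computed
for each candidate k (k = 1 meaning t-SNE of the raw MCP vectors) and the
map maximizing the average silhouette of a supplied clustering is selected
as the optimal display (ties go to the smallest k).  Comparison baselines
embed normalized or row-centered profiles instead of MCPs, and a
nearest-neighbor map links each gene to its two closest partners under any
dissimilarity measure for overlay on a 2D map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .matrix import ExpressionMatrix
from .mcp import DissimilarityMatrix, normalize_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "KCData",
    "Embedding2D",
    "MapSelection",
    "pca_mcp",
    "tsne_embed",
    "average_silhouette",
    "select_tsne_mcp_o",
    "comparison_map",
    "neighbor_map",
]

#: above this many points the Barnes-Hut approximation is used; below it the
#: exact gradient, which is permutation-equivariant bit-for-bit
_EXACT_TSNE_MAX_POINTS = 1000


@dataclass
class KCData:
    """First k principal-component scores of an MCP matrix."""

    scores: np.ndarray
    k: int
    explained_variance: np.ndarray


@dataclass
class Embedding2D:
    """A 2D map: one (x, y) row per gene, input order preserved."""

    coords: np.ndarray
    source: str
    seed: int


@dataclass
class MapSelection:
    """All candidate maps with their silhouette scores, plus the winner."""

    candidates: list[tuple[int, Embedding2D, float]]
    chosen_k: int
    chosen_map: Embedding2D

    @property
    def scores(self) -> dict[int, float]:
        return {k: s for k, _, s in self.candidates}


def _block_size(T: np.ndarray) -> int:
    n = int(round(np.sqrt(T.shape[1])))
    if n * n != T.shape[1]:
        raise ValueError(f"MCP matrix width {T.shape[1]} is not a perfect square")
    return n


def pca_mcp(T: np.ndarray, k: int) -> KCData:
    """Column-centered PCA scores of an m x n^2 MCP matrix.

    Centered MCP matrices have rank at most n - 1 (each block of each row
    sums to a constant and blocks are cyclic rotations of one another), so
    ``k`` may not exceed n - 1.
    """
    T = np.asarray(T, dtype=float)
    n = _block_size(T)
    if not 1 <= k <= n - 1:
        raise ValueError(
            f"k must be in 1..{n - 1}: centered MCP vectors of {n}-point "
            f"profiles have rank at most {n - 1}"
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(T)
    return KCData(scores=scores, k=k, explained_variance=pca.explained_variance_)


def tsne_embed(
    P: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
    max_iter: int = 1000,
    source: str = "raw",
) -> Embedding2D:
    """2D t-SNE of the rows of ``P`` (delegated to scikit-learn).

    The exact gradient is used up to 1000 points (deterministic and
    permutation-equivariant given the seed); Barnes-Hut above.  t-SNE needs
    ``m > 3 * perplexity`` neighbors to be well defined.
    """
    P = np.asarray(P, dtype=float)
    m = P.shape[0]
    if m <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {m} points; "
            f"use perplexity < {m / 3:.1f}"
        )
    method = "exact" if m <= _EXACT_TSNE_MAX_POINTS else "barnes_hut"
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
        max_iter=max_iter,
        method=method,
    )
    coords = np.asarray(tsne.fit_transform(P), dtype=float)
    return Embedding2D(coords=coords, source=source, seed=seed)


def average_silhouette(
    U: Embedding2D | np.ndarray,
    labels: np.ndarray,
    metric: str = "euclidean",
) -> float:
    """Mean silhouette width of a labeling.

    For each point, ``s = (b - a) / max(a, b)`` with ``a`` the mean distance
    to its own cluster and ``b`` the smallest mean distance to another
    cluster; members of singleton clusters score 0 by convention.  With
    ``metric="euclidean"`` the input is a 2D map (or any feature matrix);
    with ``metric="precomputed"`` it is a square dissimilarity matrix, which
    gives the measure-space silhouette of a clustering.
    """
    if isinstance(U, Embedding2D):
        X = U.coords
    elif isinstance(U, DissimilarityMatrix):
        X = U.values
        metric = "precomputed"
    else:
        X = np.asarray(U, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("average silhouette needs at least 2 non-empty clusters")
    return float(np.mean(silhouette_samples(X, labels, metric=metric)))


def select_tsne_mcp_o(
    T: np.ndarray,
    labels: np.ndarray,
    ks: list[int] | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
    max_iter: int = 1000,
    max_candidates: int = 30,
) -> MapSelection:
    """Sweep candidate maps and pick the one with the best silhouette.

    For each candidate ``k``, embed the k-component KC-data (``k = 1``
    means the raw MCP vectors, which is the only way to keep a
    one-candidate map 2D-embeddable) and score the supplied cluster labels
    on the resulting 2D map.  The candidate with the largest average
    silhouette is the optimal map; ties break toward the smallest k.  The
    default sweep is k = 1..n-1, evenly subsampled to at most
    ``max_candidates`` for large n.
    """
    T = np.asarray(T, dtype=float)
    n = _block_size(T)
    if ks is None:
        ks = list(range(1, n))
        if len(ks) > max_candidates:
            idx = np.linspace(0, len(ks) - 1, max_candidates).round().astype(int)
            ks = [ks[i] for i in sorted(set(idx.tolist()))]
    ks = sorted(set(int(k) for k in ks))
    if not ks:
        raise ValueError("empty candidate set")
    for k in ks:
        if not 1 <= k <= n - 1:
            raise ValueError(f"candidate k={k} outside 1..{n - 1}")
    candidates: list[tuple[int, Embedding2D, float]] = []
    best: tuple[float, int] | None = None
    for k in ks:
        P = T if k == 1 else pca_mcp(T, k).scores
        source = "raw-mcp" if k == 1 else f"kc-{k}"
        emb = tsne_embed(P, seed=seed, perplexity=perplexity, max_iter=max_iter, source=source)
        s_k = average_silhouette(emb, labels)
        logger.info("t-SNE-MCP-%d: average silhouette %.5f", k, s_k)
        candidates.append((k, emb, s_k))
        if best is None or s_k > best[0]:
            best = (s_k, len(candidates) - 1)
    assert best is not None
    chosen_k, chosen_map, _ = candidates[best[1]]
    return MapSelection(candidates=candidates, chosen_k=chosen_k, chosen_map=chosen_map)


def comparison_map(
    E: ExpressionMatrix | np.ndarray,
    variant: str = "tsne-n",
    seed: int = 0,
    perplexity: float = 30.0,
    max_iter: int = 1000,
) -> Embedding2D:
    """Baseline maps: t-SNE of normalized (``tsne-n``) or row-centered
    (``tsne-c``) profiles instead of MCP vectors."""
    values = E.values if isinstance(E, ExpressionMatrix) else np.asarray(E, dtype=float)
    if variant == "tsne-n":
        P = normalize_matrix(E)
    elif variant == "tsne-c":
        P = values - values.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown variant {variant!r}; choose 'tsne-n' or 'tsne-c'")
    emb = tsne_embed(P, seed=seed, perplexity=perplexity, max_iter=max_iter, source=variant)
    return emb


def neighbor_map(D: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    """Nearest and second-nearest neighbor of every gene.

    Returns an (m, 2) integer array of gene indices ordered by increasing
    off-diagonal dissimilarity; ties resolve to the lower index.  The
    relation is directed (A's nearest neighbor need not have A as its own).
    """
    d = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    m = d.shape[0]
    if m < 3:
        raise ValueError("neighbor map needs at least 3 genes")
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    order = np.argsort(work, axis=1, kind="stable")
    return order[:, :2]
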