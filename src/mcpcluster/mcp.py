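"""The multiple-cumulative-probability (MCP) transform and gene similarity measures.

An expression profile ``x = (x_1, ..., x_n)`` is first normalized into a
probability profile ``y`` (shifted into the non-negative range if needed and
divided by its sum).  For each of the ``n`` cyclic rotations ``z_s`` of
``y``, the *modified* cumulative sum is taken, in which each position
contributes only half of its own mass:

    t_j = sum_{l < j} z_l + z_j / 2.

Concatenating the ``n`` length-``n`` blocks yields the n^2-dimensional MCP
vector.  Because every rotation is represented, the transform is insensitive
to where a profile's features sit along the time axis while remaining
sensitive to their relative magnitudes; near-flat profiles, whose raw curve
shapes are dominated by noise, map to nearly identical MCP vectors.

Similarity between two genes is then the Pearson correlation of their MCP
vectors (PCC-MCP) or the Euclidean distance between them (ED-MCP).  Plain
PCC and Euclidean distance on normalized profiles are provided as baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "DegenerateProfileError",
    "DissimilarityMatrix",
    "normalize",
    "normalize_matrix",
    "cyclic_shift",
    "modified_cumsum",
    "mcp",
    "mcp_matrix",
    "pcc",
    "pcc_mcp",
    "ed_mcp",
    "pairwise_dissimilarity",
]

#: Supported dissimilarity measures: correlation or Euclidean distance on
#: MCP vectors, and the same two on raw/normalized profiles as baselines.
MEASURES = ("pcc-mcp", "pcc", "ed-mcp", "ed-n")

_DENOM_TOL = 1e-12


class DegenerateProfileError(ValueError):
    """Raised for profiles whose normalization denominator vanishes.

    This happens for an all-zero non-negative profile, or for a constant
    profile equal to its own (non-positive) minimum: after the shift the
    vector is identically zero and carries no shape information.
    """

    def __init__(self, gene_ids: list[str]):
        self.gene_ids = gene_ids
        names = ", ".join(repr(g) for g in gene_ids)
        super().__init__(f"degenerate profile (zero normalization denominator): {names}")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise gene dissimilarities under a chosen measure.

    Correlation measures use ``d = 1 - r`` (range [0, 2]); Euclidean
    measures use the L2 norm on MCP vectors or normalized profiles.
    Gene order follows the input row order.
    """

    values: np.ndarray
    measure: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values.shape[0]
        if self.values.shape != (m, m):
            raise ValueError("dissimilarity matrix must be square")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; choose from {MEASURES}")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length does not match matrix size")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def normalize(x: np.ndarray, gene_id: str = "<anonymous>") -> np.ndarray:
    """Normalize a profile into a probability vector.

    The profile is shifted by ``-min(min(x), 0)`` so that negative entries
    (log-ratio data) become admissible, then divided by its sum.  The result
    is non-negative and sums to one.

    Raises
    ------
    DegenerateProfileError
        If the post-shift sum is below 1e-12 (flat or all-zero profile).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D vector of length >= 2")
    shifted = x - min(x.min(), 0.0)
    denom = shifted.sum()
    if denom < _DENOM_TOL:
        raise DegenerateProfileError([gene_id])
    return shifted / denom


def normalize_matrix(E: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Row-wise :func:`normalize`; reports all degenerate genes at once."""
    if isinstance(E, ExpressionMatrix):
        values, gene_ids = E.values, E.gene_ids
    else:
        values = np.asarray(E, dtype=float)
        gene_ids = [str(i) for i in range(values.shape[0])]
    shifted = values - np.minimum(values.min(axis=1, keepdims=True), 0.0)
    denom = shifted.sum(axis=1, keepdims=True)
    bad = np.nonzero(denom[:, 0] < _DENOM_TOL)[0]
    if bad.size:
        raise DegenerateProfileError([gene_ids[i] for i in bad])
    return shifted / denom


def cyclic_shift(y: np.ndarray, s: int) -> np.ndarray:
    """Return the s-th cyclic permutation ``(y_s, ..., y_n, y_1, ..., y_{s-1})``.

    ``s`` is 1-based; ``s = 1`` is the identity.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not 1 <= s <= n:
        raise IndexError(f"shift index s={s} out of range 1..{n}")
    return np.roll(y, -(s - 1))


def modified_cumsum(z: np.ndarray) -> np.ndarray:
    """Modified cumulative sum of a probability vector.

    Element ``j`` is the mass strictly before position ``j`` plus half the
    mass at ``j``: ``t_j = sum_{l<j} z_l + z_j/2``.  For a probability
    vector the result lies in ``(0, 1)`` wherever ``z_j > 0``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < -1e-12):
        raise ValueError("input must be non-negative")
    if abs(z.sum() - 1.0) > 1e-9:
        raise ValueError(f"input must sum to 1 (got {z.sum()!r})")
    return np.cumsum(z) - z / 2.0


def mcp(x: np.ndarray, gene_id: str = "<anonymous>") -> np.ndarray:
    """MCP vector of a single profile: n blocks of n, one per cyclic rotation."""
    y = normalize(x, gene_id)
    n = y.size
    blocks = [modified_cumsum(cyclic_shift(y, s)) for s in range(1, n + 1)]
    return np.concatenate(blocks)


def mcp_matrix(E: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """MCP vectors for every gene, as an m x n^2 matrix (vectorized)."""
    Y = normalize_matrix(E)
    m, n = Y.shape
    out = np.empty((m, n * n), dtype=float)
    for s in range(n):
        Z = np.roll(Y, -s, axis=1)
        out[:, s * n : (s + 1) * n] = np.cumsum(Z, axis=1) - Z / 2.0
    return out


def pcc(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two vectors.

    A constant input has undefined correlation; by policy the function
    returns 0.0 and logs a warning instead of aborting, since this arises
    only in the raw-profile comparison baseline (MCP vectors of valid
    profiles are never constant).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("inputs must be 1-D vectors of equal length >= 2")
    if np.ptp(u) == 0.0 or np.ptp(v) == 0.0:
        logger.warning("constant profile in correlation; returning 0 by policy")
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def pcc_mcp(x1: np.ndarray, x2: np.ndarray) -> float:
    """Pearson correlation between the MCP vectors of two profiles."""
    return pcc(mcp(x1), mcp(x2))


def ed_mcp(x1: np.ndarray, x2: np.ndarray) -> float:
    """Euclidean distance between the MCP vectors of two profiles."""
    return float(np.linalg.norm(mcp(x1) - mcp(x2)))


def _features(E: ExpressionMatrix | np.ndarray, measure: str) -> np.ndarray:
    """Feature vectors a measure operates on: MCPs or normalized profiles."""
    if measure in ("pcc-mcp", "ed-mcp"):
        return mcp_matrix(E)
    return normalize_matrix(E)


def _correlation_dissimilarity(F: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    const = np.nonzero(np.ptp(F, axis=1) == 0.0)[0]
    if const.size:
        logger.warning(
            "constant feature rows for genes %s; their correlations set to 0",
            [gene_ids[i] for i in const],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(F)
    r[const, :] = 0.0
    r[:, const] = 0.0
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 2.0, out=d)
    return (d + d.T) / 2.0


def pairwise_dissimilarity(
    E: ExpressionMatrix | np.ndarray, measure: str = "pcc-mcp"
) -> DissimilarityMatrix:
    """All-pairs gene dissimilarity matrix under one of :data:`MEASURES`.

    ``pcc-mcp`` / ``pcc`` use ``1 - r`` on MCP vectors / normalized
    profiles; ``ed-mcp`` / ``ed-n`` use Euclidean distance on the same
    feature vectors.  Degenerate genes (un-normalizable profiles) abort
    with an error listing the offending gene IDs.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if isinstance(E, ExpressionMatrix):
        gene_ids = E.gene_ids
    else:
        gene_ids = [str(i) for i in range(np.asarray(E).shape[0])]
    F = _features(E, measure)
    if measure.startswith("pcc"):
        d = _correlation_dissimilarity(F, gene_ids)
    else:
        d = squareform(pdist(F, metric="euclidean"))
    return DissimilarityMatrix(values=d, measure=measure, gene_ids=list(gene_ids))
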