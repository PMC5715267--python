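"""Synthetic expression data: the four-group Gaussian benchmark and blob fixtures.

The benchmark data set holds 2000 five-point profiles in four groups of 500.
Group A is flat noise — every time point drawn from N(10, 2) — so its
members have equivalent magnitudes but essentially random curve shapes;
groups B, C and D carry distinct temporal signatures (a late spike, a
high-level valley, a double peak).  The second distribution parameter is
read as a standard deviation: the stated values scale linearly with the
means (e.g. N(100, 10) vs N(0.5, 0.1)), i.e. constant coefficient of
variation, which is only natural for a standard deviation.

Raw-correlation methods split group A across clusters because flat noisy
profiles have uncorrelated shapes; the MCP transform maps all of them to
near-identical vectors, which is the behavior this benchmark probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["TABLE_GROUPS", "SimulatedDataset", "simulate_dataset1", "make_blobs_fixture"]

#: (mean, standard deviation) of each group at the five time points
TABLE_GROUPS: dict[str, list[tuple[float, float]]] = {
    "A": [(10, 2), (10, 2), (10, 2), (10, 2), (10, 2)],
    "B": [(10, 2), (0.5, 0.1), (0.5, 0.1), (0.5, 0.1), (30, 3)],
    "C": [(100, 10), (60, 6), (60, 6), (60, 6), (100, 10)],
    "D": [(10, 2), (30, 3), (10, 2), (60, 6), (10, 2)],
}

GROUP_SIZE = 500


@dataclass
class SimulatedDataset:
    """The simulated benchmark: expression matrix plus true group labels."""

    matrix: ExpressionMatrix
    group: np.ndarray  # length-m array of 'A'..'D'
    seed: int


def simulate_dataset1(seed: int = 0) -> SimulatedDataset:
    """Draw the 2000 x 5 four-group Gaussian benchmark.

    Rows are grouped in blocks A, B, C, D of 500 each with gene IDs
    ``A_0001`` .. ``D_0500``; every cell is an independent normal draw with
    the group- and time-point-specific mean and standard deviation.
    Negative draws are possible and permitted (normalization shifts them).
    Identical seeds give identical matrices.
    """
    rng = np.random.default_rng(seed)
    blocks, gene_ids, groups = [], [], []
    for name, params in TABLE_GROUPS.items():
        cols = [rng.normal(mu, sd, GROUP_SIZE) for mu, sd in params]
        blocks.append(np.column_stack(cols))
        gene_ids.extend(f"{name}_{i + 1:04d}" for i in range(GROUP_SIZE))
        groups.extend([name] * GROUP_SIZE)
    matrix = ExpressionMatrix(
        values=np.vstack(blocks),
        gene_ids=gene_ids,
        sample_ids=[f"t{j + 1}" for j in range(5)],
    )
    return SimulatedDataset(matrix=matrix, group=np.asarray(groups), seed=seed)


def make_blobs_fixture(
    m: int,
    k: int,
    separation: float,
    seed: int = 0,
    n_timepoints: int = 5,
    noise: float = 0.05,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """k groups of positive profiles with a common within-group shape.

    Each group's template is the shared base profile perturbed in log-space
    by ``separation``; members multiply the template by log-normal noise
    with scale ``noise``.  ``separation = 0`` makes the groups statistically
    indistinguishable; ``separation >> noise`` makes them trivially
    recoverable.  Returns the matrix and true labels 1..k.
    """
    if not m >= k >= 2:
        raise ValueError(f"need m >= k >= 2, got m={m}, k={k}")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.5, 1.5, n_timepoints)
    templates = base * np.exp(separation * rng.normal(size=(k, n_timepoints)))
    labels = np.arange(m) % k + 1
    values = templates[labels - 1] * np.exp(noise * rng.normal(size=(m, n_timepoints)))
    matrix = ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i:04d}" for i in range(m)],
        sample_ids=[f"t{j + 1}" for j in range(n_timepoints)],
    )
    return matrix, labels
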