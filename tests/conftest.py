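import numpy as np
import pytest

from mcpcluster import ExpressionMatrix

# Three five-point profiles printed in the worked comparison of raw
# correlation vs MCP correlation: two flat-noise profiles with opposite
# curve shapes (a1, a4) and one genuinely dynamic profile (d384).
A1 = np.array([8.08, 12.36, 9.86, 10.63, 11.14])
A4 = np.array([12.39, 9.91, 9.54, 9.35, 9.41])
D384 = np.array([6.49, 37.18, 9.12, 49.39, 13.12])


@pytest.fixture
def printed_profiles():
    return A1, A4, D384


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_matrix(rng):
    """A small positive expression matrix for oracle comparisons."""
    values = rng.uniform(1.0, 20.0, size=(8, 5))
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(8)],
        sample_ids=[f"t{j}" for j in range(5)],
    )


def dissim_from_points(points):
    """Euclidean dissimilarity matrix of 1-D points, for clustering oracles."""
    points = np.asarray(points, dtype=float)
    return np.abs(points[:, None] - points[None, :])
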