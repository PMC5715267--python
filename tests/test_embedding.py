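"""Tests for PCA compression of MCP vectors, t-SNE maps, silhouette scoring,
map selection and neighbor maps."""

import numpy as np
import pytest

from mcpcluster import (
    DegenerateProfileError,
    average_silhouette,
    comparison_map,
    make_blobs_fixture,
    mcp_matrix,
    neighbor_map,
    pairwise_dissimilarity,
    pca_mcp,
    select_tsne_mcp_o,
    simulate_dataset1,
    tsne_embed,
)
from conftest import dissim_from_points


@pytest.fixture(scope="module")
def blob_mcp():
    E, truth = make_blobs_fixture(m=60, k=3, separation=3.0, seed=5)
    return mcp_matrix(E), truth, E


class TestPCAMCP:
    def test_rank_bound(self, blob_mcp):
        """Centered MCP matrices of n-point profiles have rank at most n-1."""
        T, _, _ = blob_mcp
        centered = T - T.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        assert (sv[4:] / sv[0] < 1e-8).all()  # n = 5 -> rank <= 4

    def test_full_rank_scores_preserve_distances(self, blob_mcp):
        T, _, _ = blob_mcp
        scores = pca_mcp(T, 4).scores
        centered = T - T.mean(axis=0)
        for i in (0, 7, 23):
            for j in (3, 40, 59):
                assert np.linalg.norm(scores[i] - scores[j]) == pytest.approx(
                    np.linalg.norm(centered[i] - centered[j]), abs=1e-6
                )

    def test_matches_eigendecomposition_oracle(self, rng):
        T = mcp_matrix(rng.uniform(1, 10, size=(6, 3)))
        scores = pca_mcp(T, 2).scores
        centered = T - T.mean(axis=0)
        w, v = np.linalg.eigh(centered.T @ centered)
        expected = centered @ v[:, ::-1][:, :2]
        for j in range(2):
            assert np.allclose(scores[:, j], expected[:, j], atol=1e-9) or np.allclose(
                scores[:, j], -expected[:, j], atol=1e-9
            )

    def test_explained_variance_decreasing(self, blob_mcp):
        T, _, _ = blob_mcp
        ev = pca_mcp(T, 4).explained_variance
        assert (np.diff(ev) <= 1e-12).all()

    def test_k_beyond_rank_rejected(self, blob_mcp):
        T, _, _ = blob_mcp
        with pytest.raises(ValueError, match="rank"):
            pca_mcp(T, 5)

    def test_gene_order_invariance_up_to_sign(self, blob_mcp, rng):
        T, _, _ = blob_mcp
        perm = rng.permutation(T.shape[0])
        s1 = pca_mcp(T, 3).scores
        s2 = pca_mcp(T[perm], 3).scores
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        for j in range(3):
            assert np.allclose(s1[:, j], s2[inv, j], atol=1e-8) or np.allclose(
                s1[:, j], -s2[inv, j], atol=1e-8
            )


class TestTSNE:
    def test_identical_rows_coincide(self, rng):
        P = rng.normal(size=(30, 4))
        P[17] = P[3]
        emb = tsne_embed(P, seed=0, perplexity=5)
        assert np.linalg.norm(emb.coords[17] - emb.coords[3]) < 1e-6

    def test_separated_blobs_stay_separated(self, rng):
        P = np.vstack([rng.normal(0, 1, (50, 5)), rng.normal(50, 1, (50, 5))])
        labels = np.repeat([1, 2], 50)
        emb = tsne_embed(P, seed=1, perplexity=20)
        assert average_silhouette(emb, labels) > 0.5

    def test_permutation_equivariance(self, rng):
        P = rng.normal(size=(40, 5))
        perm = rng.permutation(40)
        e1 = tsne_embed(P, seed=3, perplexity=8).coords
        e2 = tsne_embed(P[perm], seed=3, perplexity=8).coords
        inv = np.empty_like(perm)
        inv[perm] = np.arange(40)
        np.testing.assert_allclose(e1, e2[inv], atol=1e-8)

    def test_perplexity_too_large(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(rng.normal(size=(10, 3)), perplexity=30)


class TestAverageSilhouette:
    def test_extreme_separation(self, rng):
        coords = np.vstack(
            [rng.normal(0, 1e-3, (20, 2)), 100 + rng.normal(0, 1e-3, (20, 2))]
        )
        labels = np.repeat([1, 2], 20)
        assert average_silhouette(coords, labels) > 0.99

    def test_five_point_hand_computation(self):
        """Brute-force a_i/b_i on five 1-D points in two clusters."""
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [10.0, 0], [11.0, 0]])
        labels = np.array([1, 1, 1, 2, 2])
        # hand computation:
        # i=0: a=(1+2)/2=1.5, b=(10+11)/2=10.5, s=(10.5-1.5)/10.5
        # i=1: a=(1+1)/2=1.0, b=(9+10)/2=9.5,  s=8.5/9.5
        # i=2: a=(2+1)/2=1.5, b=(8+9)/2=8.5,   s=7/8.5
        # i=3: a=1.0,         b=(10+9+8)/3=9,  s=8/9
        # i=4: a=1.0,         b=(11+10+9)/3=10, s=9/10
        expected = np.mean([9 / 10.5, 8.5 / 9.5, 7 / 8.5, 8 / 9, 9 / 10])
        assert average_silhouette(coords, labels) == pytest.approx(expected, abs=1e-12)

    def test_random_labels_score_near_zero(self, rng):
        coords = rng.normal(size=(100, 2))
        labels = rng.integers(1, 3, size=100)
        assert average_silhouette(coords, labels) < 0.1

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="clusters"):
            average_silhouette(rng.normal(size=(5, 2)), np.ones(5))

    def test_singleton_cluster_scores_zero(self):
        coords = np.array([[0.0, 0], [0.1, 0], [5.0, 5]])
        labels = np.array([1, 1, 2])
        per_point_mean = average_silhouette(coords, labels)
        # the singleton contributes exactly 0 to the mean
        from sklearn.metrics import silhouette_samples

        assert silhouette_samples(coords, labels)[2] == 0.0
        assert per_point_mean < 1.0

    def test_precomputed_measure_space_silhouette(self):
        d = dissim_from_points([0, 1, 2, 10, 11, 12])
        labels = np.array([1, 1, 1, 2, 2, 2])
        s = average_silhouette(d, labels, metric="precomputed")
        assert 0.8 < s <= 1.0


class TestMapSelection:
    def test_single_candidate_is_chosen(self, blob_mcp):
        T, truth, _ = blob_mcp
        sel = select_tsne_mcp_o(T, truth, ks=[2], seed=0, perplexity=10)
        assert sel.chosen_k == 2
        assert sel.chosen_map.source == "kc-2"

    def test_scores_are_internally_consistent(self, blob_mcp):
        T, truth, _ = blob_mcp
        sel = select_tsne_mcp_o(T, truth, ks=[1, 2, 3], seed=0, perplexity=10)
        for k, emb, s_k in sel.candidates:
            assert s_k == pytest.approx(average_silhouette(emb, truth))
        assert sel.scores[sel.chosen_k] == max(sel.scores.values())
        assert all(-1 <= s <= 1 for s in sel.scores.values())

    def test_raw_mcp_candidate_for_k_one(self, blob_mcp):
        T, truth, _ = blob_mcp
        sel = select_tsne_mcp_o(T, truth, ks=[1], seed=0, perplexity=10)
        assert sel.chosen_map.source == "raw-mcp"

    def test_rerun_reproduces_selection(self, blob_mcp):
        T, truth, _ = blob_mcp
        s1 = select_tsne_mcp_o(T, truth, ks=[2, 3], seed=4, perplexity=10)
        s2 = select_tsne_mcp_o(T, truth, ks=[2, 3], seed=4, perplexity=10)
        assert s1.chosen_k == s2.chosen_k
        np.testing.assert_allclose(s1.chosen_map.coords, s2.chosen_map.coords)

    def test_invalid_candidate_rejected(self, blob_mcp):
        T, _, _ = blob_mcp
        with pytest.raises(ValueError):
            select_tsne_mcp_o(T, np.ones(T.shape[0]), ks=[5])


@pytest.fixture(scope="module")
def subsampled():
    sim = simulate_dataset1(seed=3)
    idx = np.concatenate([np.arange(g * 500, g * 500 + 120) for g in range(4)])
    return sim.matrix.values[idx], sim.group[idx]


class TestSimulatedBenchmarkMaps:
    """Seeded replication of the map-quality claims on the simulated data.

    t-SNE of a few hundred genes keeps the runtime short; group structure
    does not depend on the subsample size.
    """

    def test_chosen_map_separates_structured_groups(self, subsampled):
        values, group = subsampled
        T = mcp_matrix(values)
        labels = np.searchsorted(np.array(["A", "B", "C", "D"]), group) + 1
        sel = select_tsne_mcp_o(T, labels, ks=[1, 2, 3, 4], seed=0, perplexity=30)
        assert average_silhouette(sel.chosen_map, labels) > 0.3

    def test_normalized_profile_map_separates_groups(self, subsampled):
        values, group = subsampled
        labels = np.searchsorted(np.array(["A", "B", "C", "D"]), group) + 1
        emb = comparison_map(values, "tsne-n", seed=0, perplexity=30)
        assert average_silhouette(emb, labels) > 0.2


class TestComparisonMap:
    def test_centered_map_of_centered_input_is_identity(self, rng):
        values = rng.uniform(1, 10, size=(40, 5))
        centered = values - values.mean(axis=1, keepdims=True)
        e1 = comparison_map(values, "tsne-c", seed=2, perplexity=8)
        e2 = comparison_map(centered, "tsne-c", seed=2, perplexity=8)
        np.testing.assert_allclose(e1.coords, e2.coords, atol=1e-8)

    def test_constant_rows_rejected_on_normalized_path(self):
        values = np.vstack([np.zeros(5), np.arange(5.0), np.ones(5)])
        with pytest.raises(DegenerateProfileError):
            comparison_map(values, "tsne-n")

    def test_unknown_variant(self, rng):
        with pytest.raises(ValueError, match="variant"):
            comparison_map(rng.uniform(1, 2, (40, 4)), "umap")


class TestNeighborMap:
    def test_three_point_line(self):
        d = dissim_from_points([0, 1, 3])
        nn = neighbor_map(d)
        assert nn[0].tolist() == [1, 2]
        assert nn[1].tolist() == [0, 2]
        assert nn[2].tolist() == [1, 0]

    def test_asymmetry_witness(self):
        # 0's nearest is 1, but 1's nearest is 0 while 2's nearest is 1:
        # the relation is directed
        d = dissim_from_points([0, 1, 3])
        nn = neighbor_map(d)
        assert nn[2, 0] == 1 and nn[1, 0] == 0

    def test_ties_resolve_to_lower_index(self):
        d = dissim_from_points([0, 1, 2])
        nn = neighbor_map(d)
        assert nn[1].tolist() == [0, 2]  # both at distance 1

    def test_matches_brute_force(self, rng):
        a = rng.uniform(0, 1, (9, 9))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        nn = neighbor_map(d)
        for i in range(9):
            others = sorted((j for j in range(9) if j != i), key=lambda j: (d[i, j], j))
            assert nn[i].tolist() == others[:2]

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            neighbor_map(dissim_from_points([0, 1]))
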