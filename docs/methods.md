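# Methods

## The problem

Two gene expression profiles can represent the same biological behavior while
having very different curve shapes. The clearest case is genes whose
expression is essentially constant across time points: their measured values
are all near a common level, but measurement noise gives each profile a
random up-and-down shape, and Pearson correlation (PCC) of the raw profiles
— which responds only to shape — can be strongly negative between two such
genes while being strongly positive between a flat gene and a genuinely
dynamic one. Clustering on raw correlation therefore shatters groups of
magnitude-equivalent genes. The package addresses this with a transform that
judges profiles by the *distribution* of their mass over time points rather
than by the arrangement of that mass.

## The MCP transform

For a profile `x = (x_1, …, x_n)`:

1. **Normalize.** Shift by `-min(min_t x_t, 0)` so negative values
   (log-ratio data) become admissible, then divide by the sum. The result
   `y` is a probability vector. Profiles whose post-shift sum is below
   `1e-12` (all-zero, or constant at a non-positive value) carry no shape
   information and are rejected with an error naming the gene.
2. **Rotate.** Form the `n` cyclic permutations
   `z_s = (y_s, …, y_n, y_1, …, y_{s-1})`, `s = 1..n`.
3. **Modified cumulative sum.** For each rotation take
   `t_j = Σ_{l<j} z_l + z_j/2` — the cumulative distribution evaluated at
   the midpoint of each position's mass, so every element lies strictly in
   `(0, 1)` and the block neither starts at 0 nor ends at 1.
4. **Concatenate** the `n` blocks into the `n²`-dimensional MCP vector.

Taking all rotations makes every position's "superposition opportunity"
identical, removing the asymmetry of a single cumulative sum (where the last
position always carries weight ≈ 1). Useful consequences, all enforced as
tested invariants: the transform is invariant to positive scaling of `x`;
block `s` starts at `y_s/2` and ends at `1 − y_{s−1}/2` (cyclic index);
rotating the input rotates the blocks; near-flat profiles map to nearly
identical MCP vectors regardless of their noise shape.

Similarity measures: **PCC-MCP** (Pearson correlation of two MCP vectors)
and **ED-MCP** (their Euclidean distance), with raw-profile **PCC** and
Euclidean distance on normalized profiles (**ED-N**) as baselines.
Dissimilarity is `d = 1 − r` for the correlation measures (range [0, 2])
and the L2 distance for the Euclidean ones. A constant profile has undefined
correlation; the policy is to return `r = 0` with a logged warning rather
than abort, because this arises only in the raw-PCC baseline — MCP vectors
of valid profiles are never constant.

## icc-cluster

A deterministic k-medoid algorithm on the dissimilarity matrix:

- **Seeding (farthest-first):** the first two centers are the pair at
  maximum dissimilarity; each further center maximizes, over non-centers,
  its minimum dissimilarity to the centers already chosen.
- **Iterate:** assign every gene to its nearest center; replace each
  center by the member of its cluster minimizing the sum of dissimilarities
  to all members (the medoid); repeat until the label vector is unchanged.

All ties — the max pair, the maximin candidate, the nearest center, the
medoid sum — break toward the lowest gene index, for reproducibility.
Clusters can never empty (a center is always nearest to itself). The
objective (sum of within-cluster dissimilarity to the medoid) is
non-increasing, and the label sequence terminates; `max_iter` defaults to
100 and has never been reached on test instances (the 2000-gene benchmark
converges in ~5 iterations). Non-convergence returns the best-so-far
labeling with `converged=False` and a warning.

The **k-means baseline** mirrors the comparisons run in the source study,
which does not pin down a k-means variant; ours is Lloyd's algorithm on the
feature vectors the measure implies (MCP vectors for `*-mcp`, normalized
profiles otherwise), with squared-Euclidean distance for `ed-*` and `1 − r`
for `pcc-*`, arithmetic-mean centroids, k-means++-style seeding from the
given seed, and empty clusters reseeded to the farthest point. It is
hand-written because correlation-distance Lloyd is not available in
scikit-learn's KMeans; the details are recorded in the output metadata so
comparisons are reproducible rather than claimed to be variant-exact.

## Map generation and selection

Centered MCP matrices of `n`-point profiles have rank at most `n − 1`
(each row's blocks are cyclic rotations of a vector whose elements are
affine in the `n` normalized values and sum to a constant), so the PCA
scores at `k = n − 1` ("KC-data") are a lossless compression — verified
numerically as a singular-value bound. For each candidate `k`, a 2D t-SNE
map of the KC-data is computed (`k = 1` denotes t-SNE of the raw MCP
vectors — 1-dimensional scores are never embedded); the candidate whose map
gives the largest average silhouette of a supplied clustering is selected as
the optimal display. Silhouette: `s_i = (b_i − a_i)/max(a_i, b_i)` with
`a_i` the mean within-cluster distance and `b_i` the smallest mean distance
to another cluster, Euclidean on the 2D coordinates; singleton clusters
score 0 (common convention); ties in the argmax go to the smallest `k`. A
measure-space silhouette (distance = the clustering dissimilarity, via
`metric="precomputed"`) is also available, since map-space and measure-space
scores answer different questions. Comparison baselines embed normalized
profiles (t-SNE-N) or row-mean-centered profiles (t-SNE-C).

Numerical choices for t-SNE (delegated to scikit-learn): perplexity 30 by
default (exposed everywhere), 1000 iterations, PCA initialization, exact
gradient up to 1000 points and Barnes-Hut above. PCA initialization makes
the embedding a deterministic, permutation-equivariant function of the data:
re-running with the same inputs reproduces coordinates exactly, and
permuting gene order permutes the map. The cost is that the `seed`
parameter, while accepted and recorded in all sidecars, does not perturb the
map — we consider coordinate stability and the order contract more valuable
in a pipeline whose cluster stage is already fully deterministic. The
default candidate sweep is `k = 1..n−1`, evenly subsampled to at most 30
candidates for wide matrices.

**Neighbor maps:** for each gene, the indices of its smallest and
second-smallest off-diagonal dissimilarities (ties to the lower index). The
relation is directed. Exported as an edge list and overlaid on the chosen
map (solid = nearest, dashed = second), which shows which 2D neighbors are
truly close in the high-dimensional measure.

## Synthetic data

`simulate_dataset1` draws the four-group Gaussian benchmark: 2000 profiles
at 5 time points, 500 per group, each cell an independent normal draw.
Group A is flat — N(10, 2) at every time point — and exists to expose the
raw-correlation failure mode; B (low valley, late spike), C (high-level
valley) and D (double peak) have distinct temporal signatures. The second
distribution parameter is a standard deviation (the stated values scale
linearly with the means, i.e. constant coefficient of variation). Rows come
in blocks A, B, C, D with IDs `A_0001`..`D_0500`.

What it emulates: magnitude-equivalent noise genes vs. structured temporal
programs at realistic signal-to-noise. What it does not: count noise (SAGE
data are Poisson), probe-level artifacts, correlated errors across time
points, or cluster-size imbalance — so passing the benchmark demonstrates
the shape-invariance mechanism, not performance on any particular platform's
noise model. `make_blobs_fixture` generates k groups sharing a base profile
perturbed in log-space by a separation parameter, with log-normal
within-group noise (scale 0.05): separation 0 gives statistically
indistinguishable groups, separation ≫ noise gives trivially recoverable
ones; used to calibrate clustering and embedding tests.

At seed 1, icc-cluster with PCC-MCP at k = 4 isolates 100% of each of
groups B, C and D into three distinct clusters with 89% of group A in the
fourth (the rest joins C's cluster), while k-means with raw PCC splits
group A across all four clusters — the behavior the benchmark was designed
to discriminate. These numbers are recomputed by the test suite, not stored.

## Problem sizes and runtime

The distance matrix is O(m²) memory (2000 genes ≈ 32 MB) and the medoid
update O(Σ q²) per iteration — comfortable for the supplementary-scale
matrices (≤ 3000 genes). Map-quality tests subsample the benchmark to 120
genes per group, since t-SNE dominates runtime and the group geometry does
not depend on the subsample.

## Limitations

- The MCP transform is defined for profiles with at least one value above
  the shift baseline; degenerate profiles must be filtered upstream.
- Tie-breaking (lowest index) is a reproducibility convention; other
  implementations of the same algorithm may differ at exact ties, so
  label-level replication across implementations is only expected away from
  tie boundaries.
- t-SNE maps are for visualization; distances between well-separated map
  regions are not quantitatively meaningful, which is why cluster *selection*
  uses the silhouette of a given clustering rather than re-clustering the map.
- The candidate sweep embeds one map per k; for matrices with many samples
  this is the dominant cost and the even subsampling of candidates is a
  pragmatic cap, not a claim of optimality.
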