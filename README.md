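# mcpcluster

Shape-invariant clustering and 2D visualization of gene expression profiles
via **multiple-cumulative probabilities (MCPs)**.

Pearson correlation of raw expression profiles compares curve *shapes*. For
genes whose expression is essentially flat across time points — a large
fraction of any transcriptome — shape is noise, and raw correlation calls
two such genes dissimilar while happily pairing one of them with a strongly
dynamic gene. `mcpcluster` implements a transform that fixes this: each
profile is normalized to a probability vector `y`, every cyclic rotation
`z_s` of `y` is reduced to its *modified* cumulative sum

    t_j = Σ_{l<j} z_l + z_j / 2 ,

and the n blocks are concatenated into an n²-dimensional MCP vector.
Similarity is then Pearson correlation of MCP vectors (**PCC-MCP**) or
Euclidean distance between them (**ED-MCP**). The transform is invariant to
positive scaling and maps all near-flat profiles to nearly identical
vectors, so magnitude-equivalent genes cluster together regardless of their
noise shapes.

On top of the measure the package provides:

- **icc-cluster** — a deterministic k-medoid algorithm (farthest-first
  maximin seeding, nearest-center assignment, within-cluster medoid update,
  iterated to a fixed point) plus a k-means baseline for comparisons;
- **map selection** — PCA compression of the MCP vectors (rank ≤ n−1), a
  2D t-SNE map per candidate component count k, and automatic selection of
  the map maximizing the average silhouette
  `S_k = (1/m) Σ_i (b_i − a_i)/max(a_i, b_i)` of a given clustering;
- **neighbor maps** — each gene's nearest and second-nearest partner under
  any measure, as an edge list overlaid on the chosen map;
- a **simulator** for the four-group Gaussian benchmark (2000 × 5, groups
  A flat / B, C, D structured) so the whole pipeline is testable without
  downloads, and a `mcpcluster` CLI chaining
  simulate → distances → cluster → map → neighbors.

## Worked example

The defect of raw correlation, on three five-point profiles (two flat genes
`a1`, `a4` and one dynamic gene `d384`):

```python
>>> from mcpcluster import pcc, pcc_mcp
>>> a1   = [8.08, 12.36, 9.86, 10.63, 11.14]
>>> a4   = [12.39, 9.91, 9.54, 9.35, 9.41]
>>> d384 = [6.49, 37.18, 9.12, 49.39, 13.12]
>>> round(pcc(a1, a4), 3), round(pcc(a1, d384), 3)
(-0.741, 0.595)
>>> round(pcc_mcp(a1, a4), 3), round(pcc_mcp(a1, d384), 3)
(0.993, 0.954)
```

Raw PCC judges the two flat genes strongly *anti*-correlated (−0.741) yet
moderately similar to the dynamic gene (0.595). Under PCC-MCP the two flat
genes are nearly identical (0.993) and remain distinguishable from the
dynamic one (0.954 < 0.993, and the gap widens as dissimilarity `1 − r`).

Clustering the simulated benchmark:

```python
>>> import numpy as np
>>> from mcpcluster import simulate_dataset1, pairwise_dissimilarity, icc_cluster
>>> sim = simulate_dataset1(seed=1)
>>> D = pairwise_dissimilarity(sim.matrix, "pcc-mcp")
>>> a = icc_cluster(D, k=4)
>>> a.converged, a.n_iterations
(True, 5)
>>> for g in "ABCD":
...     vals, cnt = np.unique(a.labels[sim.group == g], return_counts=True)
...     print(g, dict(zip(vals.tolist(), cnt.tolist())))
A {3: 57, 4: 443}
B {1: 500}
C {3: 500}
D {2: 500}
```

Groups B, C and D are each isolated perfectly in their own cluster; most of
the flat group A forms the fourth cluster, with a minority joining C's —
whereas k-means on raw PCC (`kmeans_baseline(sim.matrix, 4, measure="pcc",
seed=1)`) scatters group A across all four clusters.

From the shell, the same workflow end to end:

```bash
mcpcluster simulate --dataset 1 --seed 1 --out sim.tsv
mcpcluster pipeline --input sim.tsv --measure pcc-mcp --algorithm icc \
    --k 4 --ks 1,2,3,4 --out results/run
```

which writes `run.clusters.tsv`, `run.clusters.json` (medoids, objective,
iterations), `run.map.tsv`, `run.selection.json` (per-k silhouettes `S_k`
and the chosen k), `run.neighbors.tsv` and `run.map.png`.

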