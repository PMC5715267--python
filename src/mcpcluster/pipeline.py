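"""End-to-end workflow: transform -> cluster -> map -> neighbors -> report.

Every artifact written by a run carries a short hash of the configuration
fields that determine it, so replications are a pure function of (input
file, config).  Hashes are computed per stage: the clustering artifacts of
the deterministic icc path do not depend on the map seed, so re-running the
map stage with a different seed leaves the cluster TSV byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import embedding as _embedding
from .mcp import mcp_matrix, pairwise_dissimilarity
from .matrix import ExpressionMatrix, read_expression

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "plot_map"]


@dataclass
class RunConfig:
    """Full configuration of a pipeline run; serialized into every sidecar."""

    input: str
    measure: str = "pcc-mcp"
    algorithm: str = "icc"
    k: int = 4
    ks: list[int] | None = None
    seed: int = 0
    perplexity: float = 30.0
    max_iter: int = 100
    tsne_max_iter: int = 1000
    out_prefix: str = "run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def stage_hash(self, stage: str) -> str:
        """Short hash over the config fields that determine a stage's output."""
        fields = {
            "distances": ("input", "measure"),
            "cluster": ("input", "measure", "algorithm", "k", "max_iter"),
            "map": (
                "input", "measure", "algorithm", "k", "max_iter",
                "ks", "seed", "perplexity", "tsne_max_iter",
            ),
            "neighbors": ("input", "measure"),
        }[stage]
        payload = {f: getattr(self, f) for f in fields}
        # the icc path is deterministic; only the k-means baseline consumes
        # the seed during clustering
        if stage == "cluster" and self.algorithm == "kmeans":
            payload["seed"] = self.seed
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        return digest[:12]


def _p(prefix: Path, ext: str) -> Path:
    return Path(str(prefix) + ext)


def _write_tsv(frame: pd.DataFrame, path: Path, stage_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mcpcluster config_hash={stage_hash}\n")
        frame.to_csv(fh, sep="\t", index=False)


def plot_map(
    coords: np.ndarray,
    labels: np.ndarray,
    path: str | Path,
    edges: np.ndarray | None = None,
    title: str = "",
) -> None:
    """Scatter plot of a 2D map colored by cluster, with optional
    nearest-neighbor (solid) and second-neighbor (dashed) edges."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    labels = np.asarray(labels)
    if edges is not None:
        for rank, (color, style) in enumerate([("tab:blue", "-"), ("tab:red", "--")]):
            for i in range(edges.shape[0]):
                j = edges[i, rank]
                ax.plot(
                    [coords[i, 0], coords[j, 0]],
                    [coords[i, 1], coords[j, 1]],
                    style, color=color, linewidth=0.4, alpha=0.5, zorder=1,
                )
    for lab in np.unique(labels):
        mask = labels == lab
        ax.scatter(coords[mask, 0], coords[mask, 1], s=8, label=str(lab), zorder=2)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if title:
        ax.set_title(title)
    if np.unique(labels).size <= 12:
        ax.legend(title="cluster", fontsize="small", markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig, matrix: ExpressionMatrix | None = None) -> dict:
    """Run the full workflow and write all artifacts under the out prefix.

    Artifacts: ``<prefix>.clusters.tsv``/``.clusters.json`` (labels,
    medoids, objective), ``<prefix>.map.tsv`` (2D coordinates),
    ``<prefix>.selection.json`` (per-k silhouettes and the chosen k),
    ``<prefix>.neighbors.tsv`` (two nearest neighbors per gene) and
    ``<prefix>.map.png``.  Returns the paths plus the in-memory results.
    """
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    if matrix is None:
        logger.info("reading expression matrix from %s", config.input)
        matrix = read_expression(config.input)
    logger.info("matrix: %d genes x %d samples", matrix.n_genes, matrix.n_samples)

    logger.info("stage distances: measure=%s", config.measure)
    D = pairwise_dissimilarity(matrix, config.measure)

    logger.info("stage cluster: algorithm=%s k=%d", config.algorithm, config.k)
    if config.algorithm == "icc":
        assignment = _cluster.icc_cluster(D, config.k, max_iter=config.max_iter)
    elif config.algorithm == "kmeans":
        assignment = _cluster.kmeans_baseline(
            matrix, config.k, measure=config.measure,
            seed=config.seed, max_iter=config.max_iter,
        )
    else:
        raise ValueError(f"unknown algorithm {config.algorithm!r}")

    cluster_hash = config.stage_hash("cluster")
    clusters_tsv = _p(prefix, ".clusters.tsv")
    _write_tsv(
        pd.DataFrame({"gene_id": matrix.gene_ids, "cluster": assignment.labels}),
        clusters_tsv, cluster_hash,
    )
    clusters_json = _p(prefix, ".clusters.json")
    with open(clusters_json, "w") as fh:
        json.dump(
            {
                "config_hash": cluster_hash,
                "algorithm": assignment.algorithm,
                "measure": config.measure,
                "k": assignment.k,
                "seed": config.seed if config.algorithm == "kmeans" else None,
                "medoid_gene_ids": [matrix.gene_ids[i] for i in assignment.medoids],
                "objective": assignment.objective,
                "n_iterations": assignment.n_iterations,
                "converged": assignment.converged,
                "config": config.to_dict(),
            },
            fh, indent=2,
        )

    logger.info("stage map: candidate sweep")
    T = mcp_matrix(matrix)
    selection = _embedding.select_tsne_mcp_o(
        T, assignment.labels, ks=config.ks, seed=config.seed,
        perplexity=config.perplexity, max_iter=config.tsne_max_iter,
    )
    map_hash = config.stage_hash("map")
    map_tsv = _p(prefix, ".map.tsv")
    _write_tsv(
        pd.DataFrame(
            {
                "gene_id": matrix.gene_ids,
                "x": selection.chosen_map.coords[:, 0],
                "y": selection.chosen_map.coords[:, 1],
                "cluster": assignment.labels,
            }
        ),
        map_tsv, map_hash,
    )
    selection_json = _p(prefix, ".selection.json")
    with open(selection_json, "w") as fh:
        json.dump(
            {
                "config_hash": map_hash,
                "candidates": [[k, s] for k, _, s in selection.candidates],
                "chosen_k": selection.chosen_k,
                "seed": config.seed,
                "perplexity": config.perplexity,
                "config": config.to_dict(),
            },
            fh, indent=2,
        )

    logger.info("stage neighbors")
    edges = _embedding.neighbor_map(D)
    neighbors_tsv = _p(prefix, ".neighbors.tsv")
    rows = []
    for i in range(matrix.n_genes):
        for rank in (0, 1):
            j = int(edges[i, rank])
            rows.append(
                {
                    "gene_id": matrix.gene_ids[i],
                    "neighbor_id": matrix.gene_ids[j],
                    "rank": rank + 1,
                    "dissimilarity": float(D.values[i, j]),
                }
            )
    _write_tsv(pd.DataFrame(rows), neighbors_tsv, config.stage_hash("neighbors"))

    plot_path = _p(prefix, ".map.png")
    plot_map(
        selection.chosen_map.coords, assignment.labels, plot_path, edges=edges,
        title=f"{config.algorithm}/{config.measure}, k={config.k} "
        f"(map: {selection.chosen_map.source})",
    )

    logger.info("pipeline complete: %s.*", prefix)
    return {
        "clusters_tsv": clusters_tsv,
        "clusters_json": clusters_json,
        "map_tsv": map_tsv,
        "selection_json": selection_json,
        "neighbors_tsv": neighbors_tsv,
        "plot": plot_path,
        "assignment": assignment,
        "selection": selection,
        "dissimilarity": D,
    }
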