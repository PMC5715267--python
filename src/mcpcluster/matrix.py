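"""Gene-by-sample expression matrices and delimited-text I/O.

The canonical on-disk layout is a TSV or CSV table with gene identifiers in
the first column and sample identifiers in the header row; every other cell
is numeric.  Values may be negative (e.g. log-ratio data): downstream
normalization shifts rows into the non-negative range before converting them
to probability profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "write_dissimilarity",
]


@dataclass
class ExpressionMatrix:
    """A real-valued m x n matrix of m genes measured in n samples.

    Parameters
    ----------
    values
        Float array of shape ``(m, n)``; rows are genes, columns samples.
    gene_ids
        ``m`` unique row identifiers.
    sample_ids
        ``n`` column identifiers (time points, libraries, arrays ...).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"expression matrix must be at least 2x2, got {m}x{n}")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length does not match number of rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of columns")
        seen: dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            if g in seen:
                raise ValueError(f"duplicate gene id {g!r} at rows {seen[g]} and {i}")
            seen[g] = i
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _sniff_delimiter(path: Path) -> str:
    """Auto-detect tab vs comma from the header line."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: file is empty")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample matrix from TSV/CSV.

    First column: gene IDs; header row: sample IDs.  The dialect (tab or
    comma) is auto-detected.  Missing or non-numeric cells are fatal and are
    reported with their gene and sample location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        if numeric.isna().any():
            gene = df.index[numeric.isna().to_numpy().argmax()]
            raise ValueError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        df[col] = numeric
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def write_dissimilarity(dmat, path: str | Path, sep: str = "\t") -> None:
    """Write a DissimilarityMatrix as a square table with gene IDs on both axes."""
    frame = pd.DataFrame(dmat.values, index=dmat.gene_ids, columns=dmat.gene_ids)
    frame.to_csv(path, sep=sep, index_label="gene_id")
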