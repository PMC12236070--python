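"""Expression-matrix container and on-disk formats.

Matrices are genes x cells everywhere in this package. Sparse input
(MatrixMarket coordinate + features/barcodes sidecars) is densified on
load; the workloads this package targets fit comfortably in memory.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DataError

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix"]


@dataclass
class ExpressionMatrix:
    """Genes x cells numeric matrix with row/column identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataError("expression matrix must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise DataError(f"duplicate gene identifiers: {sorted(dup)[:5]}")
        dup = _duplicates(self.cell_ids)
        if dup:
            raise DataError(f"duplicate cell identifiers: {sorted(dup)[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def _read_sidecar(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_matrix(
    path: str | Path,
    features: str | Path | None = None,
    barcodes: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX + sidecars or a dense CSV/TSV.

    MTX input is assumed genes-as-rows (use ``transpose=True`` otherwise)
    and requires ``features`` and ``barcodes`` TSV sidecars whose first
    column carries the identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if path.suffix == ".mtx":
        if features is None or barcodes is None:
            raise DataError("MTX input requires features and barcodes sidecar files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if transpose:
            mat = mat.T
        genes = _read_sidecar(Path(features))
        cells = _read_sidecar(Path(barcodes))
        if mat.shape != (len(genes), len(cells)):
            raise DataError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(genes)} features, {len(cells)} barcodes)"
            )
        return ExpressionMatrix(mat, genes, cells)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if transpose:
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str))
    )


def write_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write as dense TSV/CSV, or as MTX with ``.features.tsv``/``.barcodes.tsv``."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.values))
        stem = path.with_suffix("")
        Path(f"{stem}.features.tsv").write_text("\n".join(expr.gene_ids) + "\n")
        Path(f"{stem}.barcodes.tsv").write_text("\n".join(expr.cell_ids) + "\n")
        return
    sep = "," if path.suffix == ".csv" else "\t"
    expr.to_frame().to_csv(path, sep=sep)
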