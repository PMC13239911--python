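"""Expression-matrix I/O and preprocessing.

Matrices are stored genes x cells (rows = genes, columns = cells) throughout.
Dense CSV/TSV files carry gene identifiers in the first column and cell
identifiers in the header row; Matrix-Market files use sidecar ``genes.txt`` /
``barcodes.txt`` identifier lists.

The preprocessing pipeline mirrors the standard scRNA-seq recipe used by
LRR-type similarity learning: drop genes that are zero in more than a fixed
fraction of cells, library-size normalise each cell with a log transform,

    x_ij  <-  log2( x_ij / sum_i x_ij * scale_factor + 1 ),

then L2-normalise every cell column so that similarity learning sees
unit-scale profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("aftvlrr")

__all__ = [
    "ExpressionMatrix",
    "PreprocessConfig",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "filter_genes",
    "log_transform",
    "normalize_counts",
    "l2_normalize_cells",
    "preprocess",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells nonnegative expression matrix with identifiers.

    Attributes
    ----------
    values : ndarray of shape (m_genes, n_cells)
        Nonnegative expression values.
    gene_ids : list of str
        Unique row identifiers, length ``m_genes``.
    cell_ids : list of str
        Unique column identifiers, length ``n_cells``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValueError("need at least 1 gene and 2 cells")
        if len(self.gene_ids) != m:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != number of rows {m}"
            )
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != number of columns {n}"
            )
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression value")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class PreprocessConfig:
    """Preprocessing switches and thresholds.

    zero_fraction_threshold : genes whose fraction of zero entries strictly
        exceeds this are removed (default 0.95).
    scale_factor : library-size scale in the count normalisation (default 1e5).
    apply_l2 : L2-normalise each cell column after count normalisation.
    apply_count_scaling : apply the log library-size normalisation; when off,
        the matrix passes through unscaled (useful for already-normalised data).
    """

    zero_fraction_threshold: float = 0.95
    scale_factor: float = 1e5
    apply_l2: bool = True
    apply_count_scaling: bool = True
    removed_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction_threshold <= 1.0:
            raise ValueError("zero_fraction_threshold must be in [0, 1]")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def _check_nonnegative(values: np.ndarray, source: str) -> None:
    if np.any(values < 0):
        bad = float(values.min())
        raise ValueError(f"negative expression value ({bad}) in {source}")


def read_expression(
    path: str | Path,
    format: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV (dense) or Matrix-Market (sparse).

    Parameters
    ----------
    path : file path. Format is inferred from the suffix when ``format`` is
        None (``.csv``, ``.tsv``/``.txt``, ``.mtx``).
    format : one of {"csv", "tsv", "mtx"} to force a format.
    transpose : set when the file is stored cells x genes; the returned
        matrix is always genes x cells.

    For ``.mtx`` input, sidecar files ``genes.txt`` and ``barcodes.txt`` next
    to the matrix provide row/column identifiers; missing sidecars fall back
    to auto-generated ``gene_<i>`` / ``cell_<j>`` names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(
            suffix
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = [str(i) for i in df.index]
        cell_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(
            mat.toarray() if sparse.issparse(mat) else mat, dtype=float
        )
        gene_ids = _read_sidecar(path.parent / "genes.txt", values.shape[0], "gene")
        cell_ids = _read_sidecar(
            path.parent / "barcodes.txt", values.shape[1], "cell"
        )
    else:
        raise ValueError(f"unknown format {format!r}")

    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    _check_nonnegative(values, str(path))
    return ExpressionMatrix(values, gene_ids, cell_ids)


def _read_sidecar(path: Path, expected: int, prefix: str) -> list[str]:
    if path.exists():
        ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        if len(ids) != expected:
            raise ValueError(
                f"{path.name} lists {len(ids)} identifiers but matrix has {expected}"
            )
        return ids
    return [f"{prefix}_{i}" for i in range(expected)]


def write_expression(
    X: ExpressionMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write a matrix as CSV/TSV or Matrix-Market (with identifier sidecars)."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv"
        )
    if format in ("csv", "tsv"):
        X.to_frame().to_csv(path, sep="," if format == "csv" else "\t")
    elif format == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(X.values))
        (path.parent / "genes.txt").write_text("\n".join(X.gene_ids) + "\n")
        (path.parent / "barcodes.txt").write_text("\n".join(X.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> list[str]:
    """Read one label per line, aligned to cell order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_labels(labels: Sequence, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(l) for l in labels) + "\n")


def filter_genes(
    X: ExpressionMatrix,
    threshold: float = 0.95,
    config: PreprocessConfig | None = None,
) -> ExpressionMatrix:
    """Remove genes whose zero fraction strictly exceeds ``threshold``.

    A gene with exactly ``threshold`` zero fraction is kept (strict
    inequality).  Cell order is preserved.  Removed gene identifiers are
    logged and, when a config is supplied, appended to
    ``config.removed_genes``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    zero_frac = np.mean(X.values == 0, axis=1)
    keep = zero_frac <= threshold
    if not keep.any():
        raise ValueError("all genes filtered")
    removed = [g for g, k in zip(X.gene_ids, keep) if not k]
    if removed:
        logger.info("filter_genes removed %d genes: %s", len(removed), removed[:20])
    if config is not None:
        config.removed_genes.extend(removed)
    return ExpressionMatrix(
        X.values[keep], [g for g, k in zip(X.gene_ids, keep) if k], list(X.cell_ids)
    )


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise ``log2(x + 1)`` pseudo-count transform."""
    return ExpressionMatrix(np.log2(X.values + 1.0), list(X.gene_ids), list(X.cell_ids))


def normalize_counts(
    X: ExpressionMatrix, scale_factor: float = 1e5
) -> ExpressionMatrix:
    """Library-size normalise each cell with a log transform.

    Each entry becomes ``log2(x_ij / colsum_j * scale_factor + 1)`` with
    ``colsum_j`` the cell's total over the *input* to this call.  All-zero
    cells are left all-zero with a warning (their library size is undefined).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    _check_nonnegative(X.values, "normalize_counts input")
    colsum = X.values.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero cell column(s) left unnormalised",
            stacklevel=2,
        )
    safe = np.where(zero_cols, 1.0, colsum)
    out = np.log2(X.values / safe * scale_factor + 1.0)
    out[:, zero_cols] = 0.0
    return ExpressionMatrix(out, list(X.gene_ids), list(X.cell_ids))


def l2_normalize_cells(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every cell column to unit Euclidean norm (zero columns unchanged)."""
    norms = np.linalg.norm(X.values, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    return ExpressionMatrix(X.values / safe, list(X.gene_ids), list(X.cell_ids))


def preprocess(
    X: ExpressionMatrix, config: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Default pipeline: gene filter -> count normalisation -> per-cell L2.

    The count normalisation already contains the log transform, so the plain
    ``log_transform`` is not applied on top of it (that would double-log);
    it remains available as a standalone transform.  Column sums for the
    normalisation are computed on the filtered matrix.
    """
    config = config or PreprocessConfig()
    out = filter_genes(X, config.zero_fraction_threshold, config)
    if config.apply_count_scaling:
        out = normalize_counts(out, config.scale_factor)
    if config.apply_l2:
        out = l2_normalize_cells(out)
    return out
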