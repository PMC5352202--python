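"""Expression-matrix I/O, cell quality control and normalization.

The pipeline starts from a nonnegative genes × cells matrix on FPKM scale.
Cells that express neither of two housekeeping genes (ACTB, GAPDH by
default) are discarded; the surviving matrix is log-transformed, quantile
normalized across cells and gene-centered before it reaches the SOM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    ConfigurationError,
    EmptyResultError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_HOUSEKEEPING = ("ACTB", "GAPDH")


@dataclass
class ExpressionMatrix:
    """Nonnegative genes × cells expression values with identifiers.

    Values are on FPKM scale (or any nonnegative linear scale); rows are
    genes, columns are cells. Identifiers must be unique.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class GeneAnnotation:
    """Genomic location of genes: one (chromosome, start) record per gene.

    Starts are 0-based base-pair positions. Only the CNV stage requires
    annotation; genes missing from it are dropped there with a logged count.
    """

    table: pd.DataFrame  # columns: gene_id, chromosome, start

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "start"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"annotation needs columns {sorted(required)}")
        t = self.table
        if t["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in annotation")
        if (t["chromosome"].astype(str).str.len() == 0).any():
            raise ValidationError("empty chromosome name in annotation")
        if not np.all(np.isfinite(t["start"].to_numpy(dtype=float))):
            raise ValidationError("non-finite start in annotation")
        if (t["start"] < 0).any():
            raise ValidationError("negative start in annotation")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class QCReport:
    """Accounting of the housekeeping-gene cell filter."""

    n_input_cells: int
    n_retained: int
    removed_cell_ids: list[str]
    housekeeping_genes: list[str]

    def __post_init__(self) -> None:
        if self.n_retained + len(self.removed_cell_ids) != self.n_input_cells:
            raise ValidationError("QC report does not account for every cell")

    def to_dict(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_retained": self.n_retained,
            "removed_cell_ids": list(self.removed_cell_ids),
            "housekeeping_genes": list(self.housekeeping_genes),
        }


@dataclass
class NormalizedMatrix:
    """Log-scale, quantile-normalized, gene-centered genes × cells matrix."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


# ---------------------------------------------------------------------------
# I/O


def read_expression(
    path: str | Path,
    format: str = "tsv",
    row_names: str | Path | None = None,
    col_names: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes × cells matrix from TSV or a MatrixMarket triplet file.

    TSV: first column gene id, header row of cell ids, '.' decimal.
    mtx-triplet: coordinate MatrixMarket file plus one-id-per-line sidecars
    (``<stem>.rows.txt`` / ``<stem>.cols.txt`` next to the matrix unless
    given explicitly). Entries absent from the triplet list are zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ParseError(f"{path}: {exc}") from exc
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"{path}: duplicate gene id {dup!r}")
        return ExpressionMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))
    if format == "mtx-triplet":
        row_path = Path(row_names) if row_names else path.with_suffix("").with_name(path.stem + ".rows.txt")
        col_path = Path(col_names) if col_names else path.with_suffix("").with_name(path.stem + ".cols.txt")
        for p in (row_path, col_path):
            if not p.exists():
                raise FileNotFoundError(f"sidecar file missing: {p}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        genes = row_path.read_text().split()
        cells = col_path.read_text().split()
        return ExpressionMatrix(dense, genes, cells)
    raise ConfigurationError(f"unknown format {format!r}; use 'tsv' or 'mtx-triplet'")


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a BED-like TSV with columns gene_id, chromosome, start (0-based)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not {"gene_id", "chromosome", "start"}.issubset(df.columns):
        # headerless 3-column fallback
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "chromosome", "start"])
    return GeneAnnotation(df[["gene_id", "chromosome", "start"]].copy())


# ---------------------------------------------------------------------------
# QC


def qc_filter_cells(
    E: ExpressionMatrix,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop cells expressing none of the housekeeping genes.

    A cell is retained iff at least one housekeeping gene has value > 0.
    The gene set is unchanged; the report accounts for every removed cell.
    """
    present = [g for g in housekeeping if g in E.gene_ids]
    if not present:
        raise ConfigurationError(
            f"none of the housekeeping genes {list(housekeeping)} found in matrix"
        )
    rows = [E.gene_ids.index(g) for g in present]
    keep = (E.values[rows, :] > 0).any(axis=0)
    if not keep.any():
        raise EmptyResultError("QC filter removed every cell")
    removed = [c for c, k in zip(E.cell_ids, keep) if not k]
    filtered = ExpressionMatrix(
        E.values[:, keep],
        list(E.gene_ids),
        [c for c, k in zip(E.cell_ids, keep) if k],
    )
    report = QCReport(
        n_input_cells=E.n_cells,
        n_retained=filtered.n_cells,
        removed_cell_ids=removed,
        housekeeping_genes=present,
    )
    if removed:
        logger.info("QC removed %d of %d cells", len(removed), E.n_cells)
    return filtered, report


# ---------------------------------------------------------------------------
# Normalization


def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization across columns.

    Every column's values are replaced by the mean, over columns, of the
    sorted columns at the same rank. Ties within a column receive the mean
    of the rank-means over their tied positions, so the output is invariant
    to how a stable sort orders equal values.
    """
    X = np.asarray(X, dtype=float)
    n_rows, n_cols = X.shape
    sorted_cols = np.sort(X, axis=0)
    rank_means = sorted_cols.mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_cols):
        col = X[:, j]
        idx = np.argsort(col, kind="stable")
        s = col[idx]
        assigned = rank_means.copy()
        boundaries = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_rows]))
        for a, b in zip(starts, ends):
            if b - a > 1:
                assigned[a:b] = rank_means[a:b].mean()
        out[idx, j] = assigned
    return out


def normalize(E: ExpressionMatrix, log_transform: bool = True) -> NormalizedMatrix:
    """log10(x+1) (optional), quantile normalization, then gene centering.

    After this every gene row has mean 0 and, before centering, every cell
    shared one sorted value multiset. A constant input yields an all-zero
    matrix (no error).
    """
    if E.n_cells < 2 or E.n_genes < 2:
        raise ValidationError("normalization needs at least 2 genes and 2 cells")
    X = E.values
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in expression matrix")
    if log_transform:
        X = np.log10(X + 1.0)
    Q = quantile_normalize(X)
    centered = Q - Q.mean(axis=1, keepdims=True)
    return NormalizedMatrix(centered, list(E.gene_ids), list(E.cell_ids))


def filter_invariant_genes(N: NormalizedMatrix, min_sd: float = 0.0) -> NormalizedMatrix:
    """Remove genes whose standard deviation across cells is <= min_sd."""
    sd = N.values.std(axis=1)
    keep = sd > min_sd
    if not keep.any():
        raise EmptyResultError("all genes removed by variance filter")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("variance filter removed %d of %d genes", n_removed, N.n_genes)
    return NormalizedMatrix(
        N.values[keep, :],
        [g for g, k in zip(N.gene_ids, keep) if k],
        list(N.cell_ids),
    )
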