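"""Batch self-organizing map over gene expression profiles.

Genes are the mapped items: each gene is a point in R^(n_cells) and the
map compresses ~thousands of gene profiles into grid_rows × grid_cols
"metagene" prototype profiles (2,500 on the default 50×50 grid). A single
cell's *portrait* is its component of every metagene, displayed on the
grid; co-regulated genes end up in contiguous grid regions, so portraits
make expression programs visible as localized over-expression spots.

Training is the deterministic batch algorithm: prototypes are initialized
on the plane spanned by the first two principal components of the gene
cloud, and each epoch reassigns genes to their Euclidean best-matching
unit and replaces every prototype by the Gaussian-neighborhood-weighted
mean of the assigned genes. The neighborhood radius decays linearly from
max(grid_rows, grid_cols)/2 to 1. The seed only perturbs the
initialization by a vanishing jitter to break exact ties; identical seeds
give bit-identical maps.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class Portrait:
    """A grid-shaped view of one cell (or cell group) over all metagenes."""

    values: np.ndarray  # (grid_rows, grid_cols)
    label: str
    kind: str = "single-cell"  # single-cell | group-mean | summary

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("portrait must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("portrait values must be finite")


@dataclass
class SOMModel:
    """Trained map: unit prototypes ("metagenes") plus the gene→unit map.

    ``codebook`` is (units × cells); unit u = i * grid_cols + j sits at grid
    position (i, j). ``gene_to_unit`` assigns every input gene to exactly one
    unit; units without genes are legal and keep their prototype for
    portrait purposes.
    """

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray  # (units, n_cells)
    gene_to_unit: dict[str, int]
    cell_ids: list[str]
    training_meta: dict = field(default_factory=dict)
    checkpoints: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        units = self.grid_rows * self.grid_cols
        if self.codebook.shape[0] != units:
            raise ValidationError("codebook rows must equal grid units")
        if not np.all(np.isfinite(self.codebook)):
            raise ValidationError("codebook must be finite")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_cells(self) -> int:
        return self.codebook.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gene_to_unit)

    def unit_coords(self, unit: int) -> tuple[int, int]:
        return divmod(unit, self.grid_cols)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.codebook, columns=self.cell_ids).to_csv(
            out / "codebook.tsv", sep="\t", index_label="unit"
        )
        pd.Series(self.gene_to_unit, name="unit").rename_axis("gene_id").to_csv(
            out / "gene_to_unit.tsv", sep="\t"
        )
        meta = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            **self.training_meta,
        }
        (out / "training_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "SOMModel":
        path = Path(in_dir)
        meta = json.loads((path / "training_meta.json").read_text())
        cb = pd.read_csv(path / "codebook.tsv", sep="\t", index_col=0)
        g2u = pd.read_csv(path / "gene_to_unit.tsv", sep="\t", index_col=0)["unit"]
        grid_rows = int(meta.pop("grid_rows"))
        grid_cols = int(meta.pop("grid_cols"))
        return cls(
            grid_rows=grid_rows,
            grid_cols=grid_cols,
            codebook=cb.to_numpy(dtype=float),
            gene_to_unit={str(k): int(v) for k, v in g2u.items()},
            cell_ids=list(cb.columns),
            training_meta=meta,
        )


def _bmu(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Euclidean best-matching unit for every row of X against rows of W."""
    # ||x||^2 is constant per gene; argmin needs only the cross and unit terms
    d = (W * W).sum(axis=1)[None, :] - 2.0 * (X @ W.T)
    return np.argmin(d, axis=1)


def _grid_kernel(n: int, sigma: float) -> np.ndarray:
    pos = np.arange(n, dtype=float)
    d2 = (pos[:, None] - pos[None, :]) ** 2
    return np.exp(-d2 / (2.0 * sigma * sigma))


def train_som(
    N: NormalizedMatrix,
    grid_rows: int = 50,
    grid_cols: int = 50,
    epochs: int = 30,
    seed: int = 0,
    n_checkpoints: int = 0,
) -> SOMModel:
    """Train the batch SOM on gene profiles.

    Parameters
    ----------
    N
        Normalized genes × cells matrix; genes are the data points.
    grid_rows, grid_cols
        Grid dimensions; the default 50×50 yields 2,500 metagenes.
    epochs
        Number of batch passes; the Gaussian neighborhood radius decays
        linearly from max(grid_rows, grid_cols)/2 to 1 across them.
    seed
        Mandatory; perturbs initialization only to break exact ties.
    n_checkpoints
        If > 0, store that many evenly spaced snapshots of the gene→unit
        assignment (plus the initial one) in ``model.checkpoints`` for
        map-smoothness diagnostics.
    """
    X = np.asarray(N.values, dtype=float)
    n_genes, n_cells = X.shape
    units = grid_rows * grid_cols
    if n_cells < 2:
        raise ValidationError("SOM training needs at least 2 cells")
    if not np.all(np.isfinite(X)):
        raise ValidationError("SOM input must be finite")
    if n_genes < units:
        warnings.warn(
            f"fewer genes ({n_genes}) than grid units ({units}); "
            "many units will be empty",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    # Linear initialization on the first two principal components.
    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = Vt[: min(2, Vt.shape[0])]
    scores = Xc @ pcs.T
    span0 = np.linspace(scores[:, 0].min(), scores[:, 0].max(), grid_rows)
    if pcs.shape[0] > 1:
        span1 = np.linspace(scores[:, 1].min(), scores[:, 1].max(), grid_cols)
    else:  # degenerate rank-1 cloud
        span1 = np.zeros(grid_cols)
        pcs = np.vstack([pcs, np.zeros_like(pcs[0])])
    W = (
        mu[None, None, :]
        + span0[:, None, None] * pcs[0][None, None, :]
        + span1[None, :, None] * pcs[1][None, None, :]
    ).reshape(units, n_cells)
    scale = X.std() or 1.0
    W = W + rng.normal(0.0, 1e-9 * scale, W.shape)  # tie-break jitter

    radii = np.linspace(max(grid_rows, grid_cols) / 2.0, 1.0, max(epochs, 1))
    checkpoint_epochs: set[int] = set()
    checkpoints: list[np.ndarray] = []
    if n_checkpoints > 0:
        checkpoint_epochs = set(
            np.linspace(0, epochs - 1, min(n_checkpoints, epochs)).astype(int).tolist()
        )

    bmu = _bmu(X, W)
    for epoch in range(epochs):
        if epoch in checkpoint_epochs:
            checkpoints.append(bmu.copy())
        sums = np.zeros((units, n_cells))
        np.add.at(sums, bmu, X)
        counts = np.bincount(bmu, minlength=units).astype(float)
        # Separable Gaussian smoothing over the grid (rows then columns).
        Hr = _grid_kernel(grid_rows, radii[epoch])
        Hc = _grid_kernel(grid_cols, radii[epoch])
        S = sums.reshape(grid_rows, grid_cols, n_cells)
        C = counts.reshape(grid_rows, grid_cols)
        num = np.einsum("ab,bck->ack", Hr, S)
        num = np.einsum("cd,adk->ack", Hc, num)
        den = Hr @ C @ Hc.T
        W = (num / den[:, :, None]).reshape(units, n_cells)
        bmu = _bmu(X, W)

    if n_checkpoints > 0:
        checkpoints.append(bmu.copy())
    qe = float(np.sqrt(((X - W[bmu]) ** 2).sum(axis=1)).mean())
    model = SOMModel(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        codebook=W,
        gene_to_unit={g: int(u) for g, u in zip(N.gene_ids, bmu)},
        cell_ids=list(N.cell_ids),
        training_meta={
            "epochs": epochs,
            "seed": int(seed),
            "quantization_error": qe,
        },
        checkpoints=checkpoints,
    )
    logger.info(
        "trained %dx%d SOM on %d genes x %d cells (QE %.4f)",
        grid_rows, grid_cols, n_genes, n_cells, qe,
    )
    return model


def cell_portrait(M: SOMModel, cell_id: str) -> Portrait:
    """One cell's expression landscape: its codebook column on the grid."""
    if cell_id not in M.cell_ids:
        raise KeyError(f"unknown cell {cell_id!r}")
    col = M.cell_ids.index(cell_id)
    return Portrait(
        M.codebook[:, col].reshape(M.grid_rows, M.grid_cols),
        label=cell_id,
        kind="single-cell",
    )


def mean_portrait(M: SOMModel, cell_ids: Sequence[str]) -> Portrait:
    """Element-wise mean portrait of a cell group."""
    cell_ids = list(cell_ids)
    if not cell_ids:
        raise ValidationError("mean_portrait needs a non-empty cell list")
    cols = [M.cell_ids.index(c) for c in cell_ids]
    mean = M.codebook[:, cols].mean(axis=1).reshape(M.grid_rows, M.grid_cols)
    all_cells = len(cell_ids) == M.n_cells
    return Portrait(
        mean,
        label="all cells" if all_cells else "+".join(cell_ids[:3]) + ("..." if len(cell_ids) > 3 else ""),
        kind="summary" if all_cells else "group-mean",
    )


def map_smoothness(X: np.ndarray, bmu: np.ndarray, grid_cols: int) -> float:
    """Mean grid (Euclidean) distance from each gene's unit to the unit of
    its nearest-correlated gene.

    A smoothness diagnostic: on a well-organized map, highly correlated
    genes occupy nearby units, so this shrinks over training.
    """
    Xs = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xs, axis=1)
    norms[norms == 0] = 1.0
    Z = Xs / norms[:, None]
    R = Z @ Z.T
    np.fill_diagonal(R, -np.inf)
    partner = np.argmax(R, axis=1)
    r1, c1 = np.divmod(bmu, grid_cols)
    r2, c2 = np.divmod(bmu[partner], grid_cols)
    return float(np.sqrt((r1 - r2) ** 2 + (c1 - c2) ** 2).mean())
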