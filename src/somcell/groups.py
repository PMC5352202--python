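"""Cell-group discovery from pairwise portrait correlations.

Cells are compared by the Pearson correlation of their flattened SOM
portraits. Groups come from average-linkage hierarchical clustering on
the distance 1 - r, with the number of groups picked by the mean
silhouette width when not fixed. Groups are numbered by decreasing size
(group 1 is the largest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.metrics import silhouette_samples

from .errors import ValidationError
from .som import SOMModel

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric cells × cells Pearson correlation of portraits."""

    r: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if self.r.shape != (n, n):
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if np.any(self.r > 1 + 1e-9) or np.any(self.r < -1 - 1e-9):
            raise ValidationError("correlations must lie in [-1, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.cell_ids, columns=self.cell_ids)


@dataclass
class CellGrouping:
    """Cell → group assignment with per-cell silhouette widths.

    Groups are 1-based and ordered by decreasing size.
    """

    assignment: dict[str, int]
    k: int
    silhouette: dict[str, float]
    mean_silhouette: dict[int, float]

    def cells_in_group(self, g: int) -> list[str]:
        return [c for c, gg in self.assignment.items() if gg == g]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for g in self.assignment.values():
            out[g] = out.get(g, 0) + 1
        return dict(sorted(out.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": list(self.assignment),
                "group": list(self.assignment.values()),
                "silhouette": [self.silhouette[c] for c in self.assignment],
            }
        )


def portrait_correlations(M: SOMModel) -> CorrelationMatrix:
    """Pearson correlation of flattened portraits for every cell pair.

    A zero-variance portrait correlates 0 with everything (diagonal stays 1).
    """
    if M.n_cells < 2:
        raise ValidationError("need at least 2 cells for correlations")
    X = M.codebook.T  # cells x units
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance portraits; their correlations set to 0",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    Z = Xc / safe[:, None]
    R = Z @ Z.T
    R[zero, :] = 0.0
    R[:, zero] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(R, list(M.cell_ids))


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map raw cluster ids to 1..k ordered by decreasing cluster size."""
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels])


def cluster_cells(
    C: CorrelationMatrix,
    k: int | str = "auto",
    k_range: tuple[int, int] = (2, 8),
    linkage: str = "average",
) -> CellGrouping:
    """Hierarchical clustering of cells on d = 1 - r with silhouette-based k.

    When k = 'auto', k in k_range maximizing the overall mean silhouette
    width (computed on d) is chosen. If every pairwise distance is ~0 the
    clustering degenerates: one group, silhouette widths 0.
    """
    n = C.n_cells
    D = 1.0 - C.r
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    if isinstance(k, int) and k > n:
        raise ValidationError(f"k={k} exceeds {n} cells")
    if np.allclose(D, 0.0, atol=1e-12):
        warnings.warn("all portraits identical; returning a single group", stacklevel=2)
        return CellGrouping(
            assignment={c: 1 for c in C.cell_ids},
            k=1,
            silhouette={c: 0.0 for c in C.cell_ids},
            mean_silhouette={1: 0.0},
        )
    condensed = ssd.squareform(D, checks=False)
    Z = sch.linkage(condensed, method=linkage)

    def labels_for(kk: int) -> np.ndarray:
        return sch.fcluster(Z, t=kk, criterion="maxclust")

    if k == "auto":
        best_labels, best_k, best_score = None, 1, -np.inf
        for kk in range(k_range[0], min(k_range[1], n - 1) + 1):
            lab = labels_for(kk)
            if len(np.unique(lab)) < 2:
                continue
            sil = silhouette_samples(D, lab, metric="precomputed")
            score = sil.mean()
            if score > best_score + 1e-12:
                best_labels, best_k, best_score = lab, kk, score
        if best_labels is None:  # could not split
            best_labels = np.ones(n, dtype=int)
            best_k = 1
        labels = best_labels
        k_final = len(np.unique(labels))
        logger.info("auto-k selected k=%d (mean silhouette %.3f)", k_final, best_score)
    else:
        labels = labels_for(int(k))
        k_final = len(np.unique(labels))

    labels = _relabel_by_size(labels)
    if k_final >= 2:
        sil = silhouette_samples(D, labels, metric="precomputed")
    else:
        sil = np.zeros(n)
    assignment = {c: int(g) for c, g in zip(C.cell_ids, labels)}
    silhouette = {c: float(s) for c, s in zip(C.cell_ids, sil)}
    mean_sil = {
        int(g): float(sil[labels == g].mean()) for g in np.unique(labels)
    }
    return CellGrouping(assignment=assignment, k=int(k_final),
                        silhouette=silhouette, mean_silhouette=mean_sil)


def build_network(
    C: CorrelationMatrix,
    edge_threshold: float = 0.3,
    groups: CellGrouping | None = None,
) -> nx.Graph:
    """Similarity network: undirected edges where r >= edge_threshold.

    Purely presentational; never used for group assignment.
    """
    G = nx.Graph()
    for i, c in enumerate(C.cell_ids):
        attrs = {}
        if groups is not None:
            attrs["group"] = groups.assignment.get(c)
        G.add_node(c, **attrs)
    n = C.n_cells
    for i in range(n):
        for j in range(i + 1, n):
            if C.r[i, j] >= edge_threshold:
                G.add_edge(C.cell_ids[i], C.cell_ids[j], weight=float(C.r[i, j]))
    return G
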