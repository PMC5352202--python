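"""Copy-number inference from expression by chromosome-ordered smoothing.

Large-scale gains and losses leave a coherent footprint on the expression
of neighboring genes. The signal is recovered by log-transforming and
gene-centering expression, clipping outliers, ordering genes along each
chromosome and averaging over windows of consecutive genes (50 by
default), then re-centering each cell at its median. No reference-cell
baseline is subtracted: the short-term cultures contain no normal cells
to serve as one, and the per-cell median centering stands in for it
(documented limitation).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)


def _chrom_key(ch: str) -> tuple[int, str]:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX."""
    s = str(ch)
    m = re.fullmatch(r"(?:chr)?(\d+)", s, flags=re.IGNORECASE)
    if m:
        return (int(m.group(1)), "")
    return (10**6, s)


@dataclass
class CNVMatrix:
    """Cells × windows smoothed relative-expression values.

    ``windows`` has one row per window: chromosome, first/last gene index
    within the chromosome ordering, genomic span in base pairs. Windows
    never span two chromosomes.
    """

    values: np.ndarray  # (cells, windows)
    windows: pd.DataFrame  # chromosome, first_gene, last_gene, start_bp, end_bp
    cell_ids: list[str]
    clip: float

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.windows)):
            raise ValidationError("CNV matrix shape mismatch")

    def mean_by_chromosome(self, cells: list[str] | None = None) -> pd.Series:
        """Mean window value per chromosome, optionally over a cell subset."""
        V = self.values
        if cells is not None:
            rows = [self.cell_ids.index(c) for c in cells]
            V = V[rows, :]
        df = pd.DataFrame({"chromosome": self.windows["chromosome"],
                           "value": V.mean(axis=0)})
        return df.groupby("chromosome", sort=False)["value"].mean()

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{ch}:{int(a)}-{int(b)}"
            for ch, a, b in zip(
                self.windows["chromosome"], self.windows["start_bp"], self.windows["end_bp"]
            )
        ]
        return pd.DataFrame(self.values, index=self.cell_ids, columns=cols)


def infer_cnv(
    E: ExpressionMatrix,
    A: GeneAnnotation,
    window: int = 50,
    clip: float = 3.0,
    mode: str = "sliding",
) -> CNVMatrix:
    """Windowed relative-expression CNV estimate.

    Steps: log2(FPKM+1); per-gene centering across cells; clipping to
    ±clip; ordering genes by (chromosome, start); per-chromosome moving
    average over ``window`` consecutive genes (step 1 in 'sliding' mode,
    disjoint blocks in 'block' mode); per-cell median re-centering across
    all windows. Genes without annotation are dropped with a logged count.
    """
    if mode not in ("sliding", "block"):
        raise ValidationError(f"unknown window mode {mode!r}")
    ann = A.table.set_index("gene_id")
    annotated = [g for g in E.gene_ids if g in ann.index]
    dropped = E.n_genes - len(annotated)
    if dropped:
        logger.info("CNV: dropped %d unannotated genes", dropped)
    if not annotated:
        raise ValidationError("no annotated genes")

    idx = {g: i for i, g in enumerate(E.gene_ids)}
    order = sorted(
        annotated,
        key=lambda g: (_chrom_key(ann.at[g, "chromosome"]), float(ann.at[g, "start"]), g),
    )
    rows = np.array([idx[g] for g in order])
    chroms = np.array([str(ann.at[g, "chromosome"]) for g in order])
    starts = np.array([float(ann.at[g, "start"]) for g in order])

    L = np.log2(E.values[rows, :] + 1.0)
    L = L - L.mean(axis=1, keepdims=True)
    L = np.clip(L, -clip, clip)

    win_vals = []
    win_meta = []
    any_window = False
    for ch in dict.fromkeys(chroms):
        mask = chroms == ch
        n_ch = int(mask.sum())
        if n_ch < window:
            continue
        any_window = True
        sub = L[mask, :]  # genes on this chromosome (ordered) x cells
        st = starts[mask]
        csum = np.vstack([np.zeros((1, sub.shape[1])), np.cumsum(sub, axis=0)])
        if mode == "sliding":
            firsts = np.arange(0, n_ch - window + 1)
        else:
            firsts = np.arange(0, n_ch - window + 1, window)
        for f in firsts:
            last = f + window - 1
            win_vals.append((csum[last + 1] - csum[f]) / window)
            win_meta.append(
                {
                    "chromosome": ch,
                    "first_gene": int(f),
                    "last_gene": int(last),
                    "start_bp": float(st[f]),
                    "end_bp": float(st[last]),
                }
            )
    if not any_window:
        raise ValidationError(
            f"no chromosome has >= {window} annotated genes; use a smaller window"
        )
    V = np.array(win_vals).T  # cells x windows
    V = V - np.median(V, axis=1, keepdims=True)
    return CNVMatrix(
        values=V,
        windows=pd.DataFrame(win_meta),
        cell_ids=list(E.cell_ids),
        clip=clip,
    )
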