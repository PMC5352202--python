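"""Over-expression spot modules on the SOM grid.

A *spot* is a contiguous patch of grid units that is over-expressed in at
least a subpopulation of cells. Spots are segmented from a summary
portrait (per-unit upper quantile across cells), populated with the genes
whose best-matching unit falls inside them, and ranked by each gene's
Pearson correlation with the spot's mean per-cell profile.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage

from .errors import ValidationError
from .genesets import GeneSet
from .preprocess import NormalizedMatrix
from .som import Portrait, SOMModel

logger = logging.getLogger(__name__)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class SpotModule:
    """One contiguous over-expression module.

    ``unit_indices`` is the set of (row, col) grid coordinates of the
    spot; ``member_genes`` is the list of (gene_id, r) sorted by
    decreasing Pearson correlation with ``profile``, the spot's mean
    metagene profile across cells.
    """

    label: str
    unit_indices: set[tuple[int, int]]
    member_genes: list[tuple[str, float]] = field(default_factory=list)
    profile: np.ndarray | None = None
    peak_value: float = 0.0

    @property
    def n_units(self) -> int:
        return len(self.unit_indices)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.member_genes]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "units": sorted(self.unit_indices),
            "n_units": self.n_units,
            "peak_value": self.peak_value,
            "member_genes": [[g, float(r)] for g, r in self.member_genes],
            "profile": None if self.profile is None else [float(v) for v in self.profile],
        }


@dataclass
class SpotCountDistribution:
    """Per-cell number of active over-expression spots."""

    counts: dict[str, int]
    n_spots: int

    def per_group_summary(self, assignment: dict[str, int]) -> pd.DataFrame:
        df = pd.DataFrame(
            {"cell_id": list(self.counts), "n_spots": list(self.counts.values())}
        )
        df["group"] = df["cell_id"].map(assignment)
        return df.groupby("group")["n_spots"].agg(["mean", "median", "min", "max"])


def summary_overexpression_map(M: SOMModel, q: float = 0.98) -> Portrait:
    """Per-unit q-quantile of metagene values across cells.

    A high quantile makes units over-expressed in *any* subpopulation —
    including rare ones — visible in a single landscape.
    """
    if not (0.0 < q <= 1.0):
        raise ValidationError(f"quantile must be in (0, 1], got {q}")
    vals = np.quantile(M.codebook, q, axis=1)
    return Portrait(vals.reshape(M.grid_rows, M.grid_cols), label=f"q={q}", kind="summary")


def _profile_groups(
    coords: np.ndarray, codebook: np.ndarray, grid_cols: int, r_merge: float
) -> list[np.ndarray]:
    """Partition units into average-linkage groups of correlated profiles.

    Average linkage on the correlation distance 1 - r, cut at 1 - r_merge:
    unlike single linkage it does not chain two unrelated modules through
    the blended profiles of their boundary units.
    """
    import scipy.cluster.hierarchy as sch
    import scipy.spatial.distance as ssd

    units = [r * grid_cols + c for r, c in coords]
    P = codebook[units, :].astype(float)
    P = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(P, axis=1)
    norms[norms == 0] = 1.0
    Z = P / norms[:, None]
    R = np.clip(Z @ Z.T, -1.0, 1.0)
    D = 1.0 - (R + R.T) / 2.0
    np.fill_diagonal(D, 0.0)
    linkage = sch.linkage(ssd.squareform(D, checks=False), method="average")
    labels = sch.fcluster(linkage, t=1.0 - r_merge, criterion="distance")
    return [coords[labels == lab] for lab in np.unique(labels)]


def _split_by_cores(
    V: np.ndarray,
    mask: np.ndarray,
    core_quantile: float,
    min_units: int,
    codebook: np.ndarray | None,
    grid_cols: int,
    r_merge: float,
    core_min_units: int,
) -> list[np.ndarray]:
    """Split one foreground component along its dissimilar high-value cores.

    Core units are the component's units at or above the core_quantile of
    the component's own values (relative, so a weak module's component
    still has cores even when the map's global peaks dwarf it; 0 uses the
    whole component). With a codebook they are partitioned by
    average-linkage profile similarity (cut at r >= r_merge), so two
    co-located but uncorrelated modules — e.g. two rare-population
    modules whose territories touch — separate even when their cores form
    one spatial blob, while two local maxima of the same program always
    stay together. Without a codebook the cores fall back to spatial
    8-connected components. Core groups need >= core_min_units
    units (rare-module cores are inherently small, so this floor is
    separate from the spot-size floor); with fewer than two groups the
    component is returned unchanged. Otherwise every unit of the
    component joins its nearest core group (grid distance), and each
    resulting part is re-split into connected components so spots stay
    contiguous.
    """
    core = mask & (V >= np.quantile(V[mask], core_quantile))
    if codebook is not None:
        coords = np.argwhere(core)
        if len(coords) < 2 * core_min_units:
            return [mask]
        cores = [
            g for g in _profile_groups(coords, codebook, grid_cols, r_merge)
            if len(g) >= core_min_units
        ]
    else:
        labeled, n = scipy.ndimage.label(core, structure=_EIGHT_CONNECTED)
        cores = [
            np.argwhere(labeled == cid)
            for cid in range(1, n + 1)
            if (labeled == cid).sum() >= core_min_units
        ]
    if len(cores) < 2:
        return [mask]
    cores.sort(key=lambda g: -float(V[g[:, 0], g[:, 1]].max()))
    parts = [np.zeros_like(mask) for _ in cores]
    for r, c in np.argwhere(mask):
        d = [np.min((g[:, 0] - r) ** 2 + (g[:, 1] - c) ** 2) for g in cores]
        parts[int(np.argmin(d))][r, c] = True
    out = []
    for p in parts:
        labeled, n = scipy.ndimage.label(p, structure=_EIGHT_CONNECTED)
        for cid in range(1, n + 1):
            piece = labeled == cid
            if piece.sum() >= min_units:
                out.append(piece)
    return out if out else [mask]


def detect_spots(
    P: Portrait,
    threshold_quantile: float = 0.90,
    min_units: int = 5,
    refine_quantile: float | None = None,
    dilate: int = 0,
    codebook: np.ndarray | None = None,
    core_merge_r: float = 0.5,
    core_min_units: int = 3,
) -> list[SpotModule]:
    """Segment foreground components of a portrait into spot modules.

    Units at or above the threshold_quantile of all unit values are
    foreground; 8-connected foreground components with >= min_units units
    become spots, labeled A, B, ... by decreasing peak value.

    Two refinements, both config-exposed:

    - A refinement pass (refine_quantile, None to disable) re-examines each
      component: its units at or above that quantile *of the component's
      own values* are candidate cores, and when the cores fall into two or
      more groups with dissimilar metagene profiles — e.g. a small
      rare-population module caught in the halo of a neighboring major
      module — the component is split, each unit joining its nearest core
      group. Requires ``codebook`` (units × cells) for profile grouping;
      without it cores group by spatial adjacency. Core units whose
      profiles correlate at r >= core_merge_r count as one module and
      never split.
    - A morphological dilation (``dilate`` rings, 0 to disable) grows each
      final spot outward to absorb boundary units just below the
      threshold, compensating best-matching-unit quantization jitter at
      module edges. Units contested between spots stay unassigned, so
      spots remain pairwise disjoint.
    """
    V = P.values
    if not np.all(np.isfinite(V)):
        raise ValidationError("portrait must be finite")
    thr = np.quantile(V, threshold_quantile)
    fg = V >= thr
    labeled, n_comp = scipy.ndimage.label(fg, structure=_EIGHT_CONNECTED)
    masks = []
    for cid in range(1, n_comp + 1):
        mask = labeled == cid
        if mask.sum() < min_units:
            continue
        if refine_quantile is not None:
            masks.extend(
                _split_by_cores(V, mask, refine_quantile, min_units,
                                codebook, V.shape[1], core_merge_r,
                                core_min_units)
            )
        else:
            masks.append(mask)
    if dilate > 0 and masks:
        grown = [
            scipy.ndimage.binary_dilation(
                m, structure=_EIGHT_CONNECTED.astype(bool), iterations=dilate
            )
            for m in masks
        ]
        claimed = np.zeros_like(masks[0], dtype=int)
        for g in grown:
            claimed += g
        originals = np.zeros_like(masks[0], dtype=bool)
        for m in masks:
            originals |= m
        masks = [
            m | (g & (claimed == 1) & ~originals) for m, g in zip(masks, grown)
        ]
    comps = []
    for mask in masks:
        peak = float(V[mask].max())
        units = {(int(r), int(c)) for r, c in zip(*np.nonzero(mask))}
        comps.append((peak, units))
    comps.sort(key=lambda pc: -pc[0])
    spots = [
        SpotModule(label=chr(ord("A") + i), unit_indices=units, peak_value=peak)
        for i, (peak, units) in enumerate(comps)
    ]
    logger.info("detected %d spots at q=%.2f", len(spots), threshold_quantile)
    return spots


def attach_spot_genes(M: SOMModel, N: NormalizedMatrix, spot: SpotModule) -> SpotModule:
    """Attach member genes and the mean spot profile; rank genes by r.

    Member genes are those whose best-matching unit lies in the spot; each
    gets the Pearson correlation between its expression profile and the
    spot's per-cell mean metagene profile, sorted by decreasing r.
    """
    for r, c in spot.unit_indices:
        if not (0 <= r < M.grid_rows and 0 <= c < M.grid_cols):
            raise ValidationError(f"spot unit ({r},{c}) outside grid")
    unit_set = {r * M.grid_cols + c for r, c in spot.unit_indices}
    profile = M.codebook[sorted(unit_set), :].mean(axis=0)
    spot.profile = profile
    genes = [g for g, u in M.gene_to_unit.items() if u in unit_set]
    if not genes:
        logger.warning("spot %s has no member genes", spot.label)
        spot.member_genes = []
        return spot
    idx = {g: i for i, g in enumerate(N.gene_ids)}
    rows = np.array([idx[g] for g in genes])
    X = N.values[rows, :]
    pc = profile - profile.mean()
    pn = np.linalg.norm(pc)
    Xc = X - X.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ pc) / (xn * pn)
    r = np.nan_to_num(r, nan=0.0)
    order = np.argsort(-r, kind="stable")
    spot.member_genes = [(genes[i], float(r[i])) for i in order]
    return spot


def spots_per_cell(
    M: SOMModel,
    spots: Sequence[SpotModule],
    cell_threshold_quantile: float = 0.90,
) -> SpotCountDistribution:
    """Count, per cell, how many spots are 'on'.

    A spot is on in a cell iff the mean of the cell's portrait over the
    spot's units strictly exceeds the cell_threshold_quantile of that
    cell's own portrait values.
    """
    if not spots:
        raise ValidationError("spots_per_cell needs at least one spot")
    counts: dict[str, int] = {}
    unit_lists = [
        sorted(r * M.grid_cols + c for r, c in s.unit_indices) for s in spots
    ]
    for col, cell in enumerate(M.cell_ids):
        portrait = M.codebook[:, col]
        thr = np.quantile(portrait, cell_threshold_quantile)
        n_on = sum(1 for units in unit_lists if portrait[units].mean() > thr)
        counts[cell] = n_on
    return SpotCountDistribution(counts=counts, n_spots=len(spots))


def match_spot(spots: Sequence[SpotModule], gene_set: GeneSet) -> SpotModule | None:
    """Spot whose member genes overlap a gene set the most (ties: label order)."""
    best = None
    best_ov = 0
    for s in spots:
        ov = len(set(s.gene_ids) & gene_set.gene_ids)
        if ov > best_ov:
            best, best_ov = s, ov
    return best


def write_spots(spots: Sequence[SpotModule], out_dir: str | Path) -> None:
    """Persist spots as one JSON inventory plus a ranked-gene TSV per spot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spots.json").write_text(
        json.dumps([s.to_dict() for s in spots], indent=2)
    )
    for s in spots:
        pd.DataFrame(s.member_genes, columns=["gene_id", "r"]).to_csv(
            out / f"spot_{s.label}_genes.tsv", sep="\t", index=False
        )
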