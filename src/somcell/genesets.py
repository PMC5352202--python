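"""Gene-set machinery: GMT I/O, Fisher enrichment, GSZ profiles, set maps.

Spot gene lists are tested for enrichment with a right-tailed Fisher
exact (hypergeometric) test against the universe of genes that survived
preprocessing. Per-cell activity of a set is summarized by a gene set
Z-score (GSZ): the set's summed normalized expression standardized by a
variance estimate shrunk toward the global gene variance, which keeps
small sets from producing wild scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ParseError, ValidationError
from .preprocess import NormalizedMatrix
from .som import SOMModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    """Right-tailed Fisher exact test of a spot against one gene set.

    Contingency table over the universe: a = |spot ∩ set|, b = |spot \\ set|,
    c = |set \\ spot|, d = the rest; p = P(X >= a) under the hypergeometric
    null.
    """

    set_name: str
    spot_label: str
    a: int
    b: int
    c: int
    d: int
    p: float
    odds_ratio: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class GSZProfile:
    set_name: str
    scores: np.ndarray
    cell_ids: list[str]

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.cell_ids, name=self.set_name)


@dataclass
class GeneSetMap:
    """Per-unit counts of a gene set's members on the SOM grid."""

    set_name: str
    counts: np.ndarray  # (grid_rows, grid_cols), integers

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then tab-separated member genes.

    Duplicate members within a line are deduplicated; a line without any
    member gene is a parse error naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: list[GeneSet] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            raise ParseError(f"{path}:{ln}: gene set line without members")
        name = fields[0]
        members = frozenset(f.strip() for f in fields[2:] if f.strip())
        sets.append(GeneSet(name=name, gene_ids=members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "somcell") -> None:
    lines = [
        "\t".join([s.name, description, *sorted(s.gene_ids)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def fisher_enrichment(
    spot_members: set[str],
    gene_set: GeneSet,
    universe: set[str],
    spot_label: str = "",
) -> EnrichmentResult:
    """Right-tailed Fisher exact test of spot membership vs set membership.

    The gene set is intersected with the universe before testing; the
    odds ratio uses a 0.5 continuity correction when any table cell is 0.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not spot_members <= universe:
        raise ValidationError("spot members must be a subset of the universe")
    set_in = gene_set.gene_ids & universe
    a = len(spot_members & set_in)
    b = len(spot_members) - a
    c = len(set_in) - a
    d = len(universe) - a - b - c
    # right tail P(X >= a), hypergeometric with |universe| items, |set| marked
    p = float(scipy.stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        set_name=gene_set.name, spot_label=spot_label,
        a=a, b=b, c=c, d=d, p=p, odds_ratio=float(odds),
    )


def enrichment_table(
    spots: Sequence,
    gene_sets: Sequence[GeneSet],
    universe: set[str],
    p_threshold: float = 1e-7,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """All spot × set Fisher tests as a table; flags significance.

    Default significance is the raw-p threshold 1e-7; Benjamini-Hochberg
    adjustment is available as an option.
    """
    rows = []
    for spot in spots:
        members = set(spot.gene_ids)
        for gs in gene_sets:
            res = fisher_enrichment(members, gs, universe, spot_label=spot.label)
            rows.append(
                {
                    "spot": res.spot_label, "set": res.set_name,
                    "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                    "odds_ratio": res.odds_ratio, "p": res.p,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if bh_correct:
        m = len(df)
        order = np.argsort(df["p"].to_numpy())
        adj = np.empty(m)
        ranked = df["p"].to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        df["p_adj"] = np.minimum(adj, 1.0)
        df["significant"] = df["p_adj"] < p_threshold
    else:
        df["significant"] = df["p"] < p_threshold
    return df.sort_values(["spot", "p"]).reset_index(drop=True)


def gsz_profile(
    N: NormalizedMatrix,
    gene_set: GeneSet,
    lambda_shrink: float = 10.0,
) -> GSZProfile:
    """Per-cell GSZ score of a gene set.

    For cell c and the n set genes present in the matrix,
    ``GSZ_c = sum_g e_gc / sqrt(n * var_c~)`` where ``var_c~`` shrinks the
    cell's across-gene variance toward the global variance:
    ``var_c~ = (n * Var_genes(e_.c) + lambda * Var_global) / (n + lambda)``.
    """
    present = [g for g in N.gene_ids if g in gene_set.gene_ids]
    if not present:
        missing = sorted(gene_set.gene_ids)[:10]
        raise ValidationError(
            f"no gene of set {gene_set.name!r} present in matrix (e.g. {missing})"
        )
    idx = {g: i for i, g in enumerate(N.gene_ids)}
    rows = np.array([idx[g] for g in present])
    n = len(rows)
    sums = N.values[rows, :].sum(axis=0)
    var_cell = N.values.var(axis=0)
    var_global = N.values.var()
    var_shrunk = (n * var_cell + lambda_shrink * var_global) / (n + lambda_shrink)
    var_shrunk = np.maximum(var_shrunk, 1e-300)
    scores = sums / np.sqrt(n * var_shrunk)
    return GSZProfile(set_name=gene_set.name, scores=scores, cell_ids=list(N.cell_ids))


def flag_cells_by_gsz(profile: GSZProfile, z_thresh: float = 4.0) -> tuple[np.ndarray, float]:
    """Flag cells whose GSZ stands out from the bulk of the distribution.

    The threshold is ``median + z_thresh * 1.4826 * MAD`` of the scores: a
    robust outlier rule whose location and scale come from the bulk, so a
    rare carrier population far above it is flagged regardless of its
    size. Falls back to the standard deviation when the MAD is 0.
    Returns (boolean mask aligned with profile.cell_ids, threshold).
    """
    s = profile.scores
    med = float(np.median(s))
    mad = float(np.median(np.abs(s - med)))
    scale = 1.4826 * mad if mad > 0 else float(s.std())
    thr = med + z_thresh * scale
    return s > thr, thr


def geneset_map(M: SOMModel, gene_set: GeneSet) -> GeneSetMap:
    """Count set members per SOM unit (genes absent from the model logged)."""
    counts = np.zeros(M.n_units, dtype=int)
    absent = 0
    for g in gene_set.gene_ids:
        u = M.gene_to_unit.get(g)
        if u is None:
            absent += 1
        else:
            counts[u] += 1
    if absent:
        logger.info("gene set %s: %d genes absent from model", gene_set.name, absent)
    return GeneSetMap(
        set_name=gene_set.name,
        counts=counts.reshape(M.grid_rows, M.grid_cols),
    )
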