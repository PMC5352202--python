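"""End-to-end orchestration: QC → normalize → SOM → spots → groups →
gene sets → CNV, with persisted intermediates and a machine-readable
report. Identical config + seed gives bit-stable outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import CNVMatrix, infer_cnv
from .errors import ConfigurationError, SomcellError, ValidationError
from .genesets import (
    GeneSet,
    enrichment_table,
    gsz_profile,
)
from .groups import (
    CellGrouping,
    CorrelationMatrix,
    build_network,
    cluster_cells,
    portrait_correlations,
)
from .preprocess import (
    ExpressionMatrix,
    GeneAnnotation,
    NormalizedMatrix,
    QCReport,
    filter_invariant_genes,
    normalize,
    qc_filter_cells,
    read_annotation,
    read_expression,
)
from .genesets import read_gmt
from .som import Portrait, SOMModel, mean_portrait, train_som
from .spots import (
    SpotCountDistribution,
    SpotModule,
    attach_spot_genes,
    detect_spots,
    spots_per_cell,
    summary_overexpression_map,
    write_spots,
)

logger = logging.getLogger(__name__)


class StageError(SomcellError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineParams:
    """Every tunable of the analysis stages, with the pipeline defaults."""

    log_transform: bool = True
    min_sd: float = 0.0
    housekeeping: tuple[str, ...] = ("ACTB", "GAPDH")
    grid_rows: int = 50
    grid_cols: int = 50
    epochs: int = 30
    summary_quantile: float = 0.98
    spot_threshold_quantile: float = 0.85
    min_spot_units: int = 5
    refine_quantile: float | None = 0.0
    spot_dilate: int = 1
    core_merge_r: float = 0.5
    core_min_units: int = 3
    cell_threshold_quantile: float = 0.90
    k: int | str = "auto"
    k_min: int = 2
    k_max: int = 8
    linkage: str = "average"
    edge_threshold: float = 0.3
    lambda_shrink: float = 10.0
    enrichment_p: float = 1e-7
    bh_correct: bool = False
    cnv_window: int = 50
    cnv_clip: float = 3.0
    cnv_mode: str = "sliding"
    min_major_genes: int = 40
    seed: int = 0


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    matrix_path: str
    out_dir: str
    matrix_format: str = "tsv"
    annotation_path: str | None = None
    gmt_path: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def to_flat_dict(self) -> dict:
        d = {
            "matrix_path": self.matrix_path,
            "out_dir": self.out_dir,
            "matrix_format": self.matrix_format,
            "annotation_path": self.annotation_path,
            "gmt_path": self.gmt_path,
        }
        for f in dataclasses.fields(PipelineParams):
            v = getattr(self.params, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a flat mapping")
        own = {"matrix_path", "out_dir", "matrix_format", "annotation_path", "gmt_path"}
        param_names = {f.name for f in dataclasses.fields(PipelineParams)}
        unknown = set(raw) - own - param_names
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "matrix_path" not in raw or "out_dir" not in raw:
            raise ConfigurationError(f"{path}: matrix_path and out_dir are required")
        params_kwargs = {}
        for name in param_names:
            if name in raw:
                v = raw[name]
                params_kwargs[name] = tuple(v) if isinstance(v, list) else v
        return cls(
            matrix_path=raw["matrix_path"],
            out_dir=raw["out_dir"],
            matrix_format=raw.get("matrix_format", "tsv"),
            annotation_path=raw.get("annotation_path"),
            gmt_path=raw.get("gmt_path"),
            params=PipelineParams(**params_kwargs),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All in-memory artifacts of one analysis run."""

    expression: ExpressionMatrix
    qc_report: QCReport
    normalized: NormalizedMatrix
    model: SOMModel
    summary_map: Portrait
    spots: list[SpotModule]
    correlations: CorrelationMatrix
    grouping: CellGrouping
    spot_counts: SpotCountDistribution | None
    enrichment: pd.DataFrame | None = None
    gsz: pd.DataFrame | None = None
    cnv: CNVMatrix | None = None

    def major_spots(self, min_genes: int = 40) -> list[SpotModule]:
        """Spots carrying at least min_genes member genes."""
        return [s for s in self.spots if len(s.member_genes) >= min_genes]

    def group_percentages(self) -> dict[int, float]:
        sizes = self.grouping.sizes()
        total = sum(sizes.values())
        return {g: 100.0 * n / total for g, n in sizes.items()}


@dataclass
class RunReport:
    """Machine-readable summary mirroring a spot/group inventory table."""

    qc: dict
    n_groups: int
    group_sizes: dict[int, int]
    group_percentages: dict[int, float]
    spots: list[dict]
    enrichment: list[dict]
    gsz_summary: list[dict]
    cnv_summary: dict
    version: str
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)


def analyze(
    E: ExpressionMatrix,
    annotation: GeneAnnotation | None = None,
    gene_sets: Sequence[GeneSet] | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run every analysis stage on an in-memory matrix."""
    p = params or PipelineParams()

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except SomcellError as exc:
            raise StageError(name, exc) from exc
        logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
        return out

    filtered, qc = stage("qc", qc_filter_cells, E, p.housekeeping)
    norm = stage("normalize", normalize, filtered, p.log_transform)
    norm = stage("variance", filter_invariant_genes, norm, p.min_sd)
    model = stage(
        "som", train_som, norm,
        grid_rows=p.grid_rows, grid_cols=p.grid_cols,
        epochs=p.epochs, seed=p.seed,
    )
    summary = stage("summary_map", summary_overexpression_map, model, p.summary_quantile)
    spots = stage(
        "spots", detect_spots, summary,
        p.spot_threshold_quantile, p.min_spot_units, p.refine_quantile,
        p.spot_dilate, model.codebook, p.core_merge_r, p.core_min_units,
    )
    for s in spots:
        stage("spot_genes", attach_spot_genes, model, norm, s)
    corr = stage("correlations", portrait_correlations, model)
    grouping = stage(
        "groups", cluster_cells, corr,
        k=p.k, k_range=(p.k_min, p.k_max), linkage=p.linkage,
    )
    spot_counts = (
        stage("spot_counts", spots_per_cell, model, spots, p.cell_threshold_quantile)
        if spots else None
    )

    enrichment = gsz = cnv = None
    if gene_sets:
        universe = set(norm.gene_ids)
        enrichment = stage(
            "enrichment", enrichment_table, spots, gene_sets, universe,
            p.enrichment_p, p.bh_correct,
        )
        cols = {}
        for gs in gene_sets:
            try:
                cols[gs.name] = gsz_profile(norm, gs, p.lambda_shrink).scores
            except ValidationError:
                logger.warning("gene set %s absent from matrix; GSZ skipped", gs.name)
        gsz = pd.DataFrame(cols, index=norm.cell_ids)
    if annotation is not None:
        cnv = stage("cnv", infer_cnv, filtered, annotation,
                    p.cnv_window, p.cnv_clip, p.cnv_mode)

    return PipelineResult(
        expression=filtered, qc_report=qc, normalized=norm, model=model,
        summary_map=summary, spots=spots, correlations=corr,
        grouping=grouping, spot_counts=spot_counts,
        enrichment=enrichment, gsz=gsz, cnv=cnv,
    )


def build_report(result: PipelineResult, config_hash: str = "") -> RunReport:
    sizes = result.grouping.sizes()
    pct = result.group_percentages()
    spots = [
        {
            "label": s.label,
            "n_units": s.n_units,
            "n_genes": len(s.member_genes),
            "top_10_genes": [g for g, _ in s.member_genes[:10]],
        }
        for s in result.spots
    ]
    enr = []
    if result.enrichment is not None and not result.enrichment.empty:
        enr = result.enrichment[result.enrichment["significant"]].to_dict("records")
    gszs = []
    if result.gsz is not None:
        for name in result.gsz.columns:
            v = result.gsz[name]
            gszs.append({"set": name, "mean": float(v.mean()), "max": float(v.max())})
    cnv_summary = {}
    if result.cnv is not None:
        cnv_summary = {
            str(ch): float(v) for ch, v in result.cnv.mean_by_chromosome().items()
        }
    return RunReport(
        qc=result.qc_report.to_dict(),
        n_groups=result.grouping.k,
        group_sizes=sizes,
        group_percentages=pct,
        spots=spots,
        enrichment=enr,
        gsz_summary=gszs,
        cnv_summary=cnv_summary,
        version=__version__,
        config_hash=config_hash,
    )


def persist_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "qc_report.json").write_text(json.dumps(result.qc_report.to_dict(), indent=2))
    result.normalized.to_frame().to_csv(out / "normalized.tsv", sep="\t",
                                        index_label="gene_id")
    result.model.save(out / "som")
    write_spots(result.spots, out / "spots")
    result.grouping.to_frame().to_csv(out / "groups.tsv", sep="\t", index=False)
    result.correlations.to_frame().to_csv(out / "portrait_correlations.tsv", sep="\t")
    edges = build_network(result.correlations, groups=result.grouping)
    pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in edges.edges(data=True)],
        columns=["cell_a", "cell_b", "r"],
    ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    if result.spot_counts is not None:
        pd.Series(result.spot_counts.counts, name="n_spots").rename_axis("cell_id") \
            .to_csv(out / "spots_per_cell.tsv", sep="\t")
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if result.gsz is not None:
        result.gsz.rename_axis("cell_id").to_csv(out / "gsz_profiles.tsv", sep="\t")
    if result.cnv is not None:
        result.cnv.to_frame().rename_axis("cell_id").to_csv(out / "cnv.tsv", sep="\t")
        result.cnv.windows.to_csv(out / "cnv_windows.tsv", sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Load inputs per config, analyze, persist, and report."""
    E = read_expression(cfg.matrix_path, format=cfg.matrix_format)
    annotation = read_annotation(cfg.annotation_path) if cfg.annotation_path else None
    gene_sets = None
    if cfg.gmt_path:
        try:
            gene_sets = read_gmt(cfg.gmt_path)
        except (FileNotFoundError, SomcellError) as exc:
            raise StageError("genesets", exc) from exc
    result = analyze(E, annotation=annotation, gene_sets=gene_sets, params=cfg.params)
    out = Path(cfg.out_dir)
    persist_result(result, out)
    report = build_report(result, config_hash=cfg.config_hash())
    (out / "report.json").write_text(report.to_json())
    cfg.save(out / "config.yaml")
    return report


# ---------------------------------------------------------------------------
# Helpers for locating planted programs in a finished run


def spot_activity(result: PipelineResult, cell_threshold_quantile: float = 0.90) -> pd.DataFrame:
    """Boolean cells × spots table of per-cell spot 'on' states."""
    M = result.model
    cols = {}
    for s in result.spots:
        units = sorted(r * M.grid_cols + c for r, c in s.unit_indices)
        on = []
        for col in range(M.n_cells):
            portrait = M.codebook[:, col]
            thr = np.quantile(portrait, cell_threshold_quantile)
            on.append(portrait[units].mean() > thr)
        cols[s.label] = on
    return pd.DataFrame(cols, index=M.cell_ids)


def identify_program_spot(result: PipelineResult, gene_set: GeneSet) -> SpotModule | None:
    """Spot with the strongest Fisher enrichment of the set (min right-tail p)."""
    from .genesets import fisher_enrichment

    universe = set(result.normalized.gene_ids)
    best, best_p = None, np.inf
    for s in result.spots:
        res = fisher_enrichment(set(s.gene_ids), gene_set, universe, spot_label=s.label)
        if res.p < best_p:
            best, best_p = s, res.p
    return best


def identify_program_group(result: PipelineResult, spot: SpotModule) -> int:
    """Group whose mean portrait peaks over the spot's units."""
    M = result.model
    units = sorted(r * M.grid_cols + c for r, c in spot.unit_indices)
    best_g, best_v = None, -np.inf
    for g in sorted(set(result.grouping.assignment.values())):
        cells = result.grouping.cells_in_group(g)
        v = mean_portrait(M, cells).values.reshape(-1)[units].mean()
        if v > best_v:
            best_g, best_v = g, v
    return int(best_g)


# ---------------------------------------------------------------------------
# Joint multi-culture analysis


def joint_analysis(
    matrices: Sequence[ExpressionMatrix],
    labels: Sequence[str],
    annotation: GeneAnnotation | None = None,
    gene_sets: Sequence[GeneSet] | None = None,
    params: PipelineParams | None = None,
) -> tuple[PipelineResult, pd.DataFrame]:
    """Re-train the map on the concatenated cultures and compare them.

    Genes are intersected across cultures (error below 100 shared genes),
    cells are tagged with their culture of origin, and the whole pipeline
    runs once on the union. Returns the result plus a per-culture spot
    activity table: the fraction of each culture's cells with each spot on.
    """
    if len(matrices) < 2:
        raise ValidationError("joint analysis needs at least 2 matrices")
    if len(labels) != len(matrices):
        raise ValidationError("one label per matrix required")
    shared = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        shared &= set(m.gene_ids)
    if len(shared) < 100:
        raise ValidationError(f"gene intersection too small ({len(shared)} < 100)")
    genes = [g for g in matrices[0].gene_ids if g in shared]
    blocks, cells, origin = [], [], []
    for m, lab in zip(matrices, labels):
        idx = [m.gene_ids.index(g) for g in genes]
        blocks.append(m.values[idx, :])
        cells.extend(f"{lab}:{c}" for c in m.cell_ids)
        origin.extend([lab] * m.n_cells)
    E = ExpressionMatrix(np.hstack(blocks), genes, cells)
    p = params or PipelineParams()
    result = analyze(E, annotation=annotation, gene_sets=gene_sets, params=p)

    activity = spot_activity(result, p.cell_threshold_quantile)
    culture_of = {f"{lab}:{c}": lab for m, lab in zip(matrices, labels) for c in m.cell_ids}
    activity["culture"] = [culture_of[c] for c in activity.index]
    per_culture = activity.groupby("culture").mean()
    return result, per_culture
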