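"""Scoring of pipeline runs against synthetic-culture ground truth.

These helpers implement the recovery measurements used to validate the
pipeline on the preset cultures: locating the spot that corresponds to a
planted program, flagging rare-subpopulation cells from GSZ profiles,
and reading off group compositions.
"""

from __future__ import annotations

import numpy as np

from .genesets import GeneSet, flag_cells_by_gsz, gsz_profile
from .pipeline import (
    PipelineParams,
    PipelineResult,
    analyze,
    identify_program_group,
    identify_program_spot,
)
from .spots import match_spot
from .synthetic import GroundTruth, generate, preset


def run_preset(name: str, seed: int | None = None) -> tuple[PipelineResult, GroundTruth]:
    """Generate one preset culture and run the full analysis on it.

    The generator seed and the SOM seed are both set to ``seed`` (the
    preset's documented default when None).
    """
    cfg = preset(name)
    if seed is not None:
        cfg.seed = seed
    E, annotation, truth = generate(cfg)
    result = analyze(
        E, annotation=annotation, gene_sets=truth.to_gene_sets(),
        params=PipelineParams(seed=cfg.seed),
    )
    return result, truth


def truth_set(truth: GroundTruth, program: str) -> GeneSet:
    return GeneSet(program, frozenset(truth.gene_programs[program]))


def rare_flag_percentage(
    result: PipelineResult, truth: GroundTruth, program: str, via_spot: bool = True
) -> float:
    """Percentage of cells flagged as expressing a rare program.

    With ``via_spot`` the flagging runs on the GSZ of the member genes of
    the detected spot that best overlaps the program's truth set (the
    operational route when no truth is available a spot stands in for the
    module); otherwise directly on the truth set's GSZ profile.
    """
    if via_spot:
        spot = match_spot(result.spots, truth_set(truth, program))
        if spot is None:
            return 0.0
        gene_set = GeneSet(f"spot_{spot.label}", frozenset(spot.gene_ids))
    else:
        gene_set = truth_set(truth, program)
    profile = gsz_profile(result.normalized, gene_set)
    mask, _ = flag_cells_by_gsz(profile)
    return 100.0 * float(mask.mean())


def proliferation_percentage(result: PipelineResult, truth: GroundTruth) -> float:
    """Size (%) of the group whose mean portrait peaks in the spot
    enriched for the planted proliferation set."""
    spot = identify_program_spot(result, truth_set(truth, "proliferation"))
    group = identify_program_group(result, spot)
    return result.group_percentages()[group]


def abc_genes_recovered(result: PipelineResult, truth: GroundTruth) -> int:
    """ABC-family marker genes among the members of the rare-module spot."""
    spot = match_spot(result.spots, truth_set(truth, "ABC_ALDH"))
    if spot is None:
        return 0
    return len(set(spot.gene_ids) & set(truth.gene_programs["ABC_like"]))


def major_spot_matches(
    result: PipelineResult, truth: GroundTruth, n_major: int = 4, top_n: int = 20
) -> list[tuple[str, str, float]]:
    """Match the n_major largest spots (by member genes) to planted programs.

    Returns (spot label, best program, top-N purity) per spot, where
    purity is the fraction of the spot's top-N ranked genes belonging to
    the best-matching planted program.
    """
    majors = sorted(result.spots, key=lambda s: -len(s.member_genes))[:n_major]
    out = []
    programs = {
        name: set(genes)
        for name, genes in truth.gene_programs.items()
        if name not in ("ABC_like", "ALDH_like")
    }
    for s in majors:
        top = set(s.gene_ids[:top_n])
        if not top:
            continue
        best = max(programs, key=lambda p: len(top & programs[p]))
        purity = len(top & programs[best]) / min(top_n, len(s.member_genes))
        out.append((s.label, best, purity))
    return out


def planted_group_ari(result: PipelineResult, truth: GroundTruth) -> float:
    """Adjusted Rand index between discovered groups and planted labels."""
    from sklearn.metrics import adjusted_rand_score

    cells = list(result.grouping.assignment)
    return float(
        adjusted_rand_score(
            [truth.cell_groups[c] for c in cells],
            [result.grouping.assignment[c] for c in cells],
        )
    )
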