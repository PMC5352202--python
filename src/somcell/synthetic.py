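"""Synthetic single-cell expression matrices with full ground truth.

The generator emulates the statistical structure of FPKM-scale
single-cell RNA-seq of melanoma short-term cultures profiled on 96-well
microfluidic chips: a handful of dominant expression programs that
partition the cells into major groups, one program shared across two
groups, two rare subpopulations (an ABC-transporter/ALDH-like module in
~10% of cells and a KDM5B-like module in ~7%), chamber failures that
express no housekeeping genes, log-normal library-size variation,
expression-dependent dropout, and optional clonal chromosome-scale
copy-number events. Every latent label is returned as ground truth so
each pipeline stage can be scored against what was planted.

Model
-----
For gene g in cell c the log-scale latent is
``L_gc = mu_g + effect * a_pc * carrier(g, c) + shift_gc * ln 2 + N(0, noise_sigma)``
with ``mu_g ~ N(base_log_mean, base_log_sd)`` (natural log) and a
per-cell program activity ``a_pc ~ logN(0, activity_sigma)`` so that
program expression is graded across carrier cells rather than binary. The emitted
value is ``exp(L_gc) * lib_c`` with ``lib_c ~ logN(0, library_size_sigma)``,
zeroed with probability ``min(1, dropout_rate * exp(-L_gc))`` so weakly
expressed genes drop out more. Housekeeping genes are modeled as highly
expressed and exempt from dropout; QC-failure chambers have both forced
to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .genesets import GeneSet, write_gmt
from .preprocess import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

HOUSEKEEPING_GENES = ("ACTB", "GAPDH")


@dataclass(frozen=True)
class ProgramSpec:
    """One planted expression program.

    A program with ``overlap_with`` empty defines a major cell group; the
    group-defining fractions must sum to <= 1. A program naming other
    programs in ``overlap_with`` is expressed in the union of those
    programs' cells instead of defining its own group (e.g. an oxidative-
    phosphorylation module active in two groups at once). ``subsets``
    optionally splits the program's genes into labeled marker families
    (e.g. 16 ABC-transporter-like + 8 ALDH-like genes).
    """

    name: str
    n_genes: int
    cell_fraction: float
    effect: float = 2.0  # natural-log mean shift in carrier cells
    overlap_with: tuple[str, ...] = ()
    subsets: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.cell_fraction <= 1.0):
            raise ValidationError(f"{self.name}: cell_fraction outside [0, 1]")
        if self.n_genes < 1:
            raise ValidationError(f"{self.name}: n_genes must be positive")
        if self.subsets and sum(n for _, n in self.subsets) != self.n_genes:
            raise ValidationError(f"{self.name}: subset sizes must sum to n_genes")


@dataclass(frozen=True)
class CNVEvent:
    """A subclonal copy-number event on one chromosome.

    Events sharing a non-None ``clone`` tag hit the same randomly drawn
    carrier cells (one subclone carrying several events). Expression-based
    CNV inference without a reference baseline can only resolve events
    that differ *between* cells, so carrier fractions of 1.0 leave no
    footprint after per-gene centering.
    """

    chromosome: str
    cell_fraction: float
    log2_shift: float
    clone: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.cell_fraction <= 1.0):
            raise ValidationError("CNV cell_fraction outside (0, 1]")


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic culture."""

    n_genes: int = 2000
    n_cells: int = 96
    programs: list[ProgramSpec] = field(default_factory=list)
    rare_programs: list[ProgramSpec] = field(default_factory=list)
    n_qc_fail: int = 4
    dropout_rate: float = 0.55
    library_size_sigma: float = 0.3
    noise_sigma: float = 0.4
    activity_sigma: float = 0.35
    base_log_mean: float = 0.0
    base_log_sd: float = 1.2
    housekeeping_log_mean: float = 5.0
    n_chromosomes: int = 20
    cnv_events: list[CNVEvent] = field(default_factory=list)
    seed: int = 0
    gene_seed: int = 7777  # baseline expression is a property of the genome

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        group_frac = sum(p.cell_fraction for p in self.programs if not p.overlap_with)
        if group_frac > 1.0 + 1e-9:
            raise ValidationError(
                f"mutually exclusive program fractions sum to {group_frac:.3f} > 1"
            )
        for p in self.rare_programs:
            if p.overlap_with:
                raise ValidationError("rare programs cannot overlap groups")
        n_program_genes = sum(
            p.n_genes for p in [*self.programs, *self.rare_programs]
        )
        if n_program_genes + len(HOUSEKEEPING_GENES) > self.n_genes:
            raise ValidationError("program genes exceed n_genes")
        if self.n_qc_fail >= self.n_cells:
            raise ValidationError("n_qc_fail must be smaller than n_cells")
        names = [p.name for p in [*self.programs, *self.rare_programs]]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate program names")
        groups = {p.name for p in self.programs if not p.overlap_with}
        for p in self.programs:
            for o in p.overlap_with:
                if o not in groups:
                    raise ValidationError(
                        f"{p.name}: overlap_with references unknown group program {o!r}"
                    )


@dataclass
class GroundTruth:
    """Everything that was planted, keyed the way the scorer needs it."""

    cell_groups: dict[str, int]  # cell -> major group (1 = largest; 0 = none)
    group_names: dict[int, str]  # group index -> program name
    rare_carriers: dict[str, set[str]]  # rare program -> carrier cells
    gene_programs: dict[str, list[str]]  # program / subset -> gene ids
    cnv_carriers: dict[str, set[str]]  # chromosome -> carrier cells
    qc_fail_cells: list[str]
    mu_g: dict[str, float]
    library_factors: dict[str, float]

    def to_gene_sets(self) -> list[GeneSet]:
        return [
            GeneSet(name=name, gene_ids=frozenset(genes))
            for name, genes in self.gene_programs.items()
        ]

    def group_of_program(self, program: str) -> int:
        for g, name in self.group_names.items():
            if name == program:
                return g
        raise KeyError(program)


def _allocate_counts(fractions: list[float], total: int) -> list[int]:
    """Largest-remainder rounding of fractions * total."""
    raw = [f * total for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = int(round(sum(fractions) * total)) - sum(counts)
    remainders = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for i in range(short):
        counts[remainders[i]] += 1
    return counts


def generate(
    config: SyntheticConfig,
    out_dir: str | Path | None = None,
) -> tuple[ExpressionMatrix, GeneAnnotation, GroundTruth]:
    """Draw one synthetic culture; optionally persist it.

    When ``out_dir`` is given, writes matrix.tsv, annotation.tsv,
    truth_sets.gmt and truth_labels.tsv there. All randomness comes from
    ``config.seed``; identical configs give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_cells = config.n_genes, config.n_cells

    # --- gene inventory -------------------------------------------------
    gene_ids: list[str] = list(HOUSEKEEPING_GENES)
    gene_programs: dict[str, list[str]] = {}
    all_programs = [*config.programs, *config.rare_programs]
    for p in all_programs:
        names: list[str] = []
        if p.subsets:
            for sub_label, sub_n in p.subsets:
                sub_names = [f"{sub_label}_g{i:03d}" for i in range(1, sub_n + 1)]
                gene_programs[sub_label] = sub_names
                names.extend(sub_names)
        else:
            names = [f"{p.name}_g{i:03d}" for i in range(1, p.n_genes + 1)]
        gene_programs[p.name] = names
        gene_ids.extend(names)
    n_bg = n_genes - len(gene_ids)
    gene_ids.extend(f"BG_g{i:04d}" for i in range(1, n_bg + 1))
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # --- cell inventory -------------------------------------------------
    cell_ids = [f"C{i:03d}" for i in range(1, n_cells + 1)]
    group_programs = [p for p in config.programs if not p.overlap_with]
    order = sorted(range(len(group_programs)),
                   key=lambda i: -group_programs[i].cell_fraction)
    ordered = [group_programs[i] for i in order]
    counts = _allocate_counts([p.cell_fraction for p in ordered], n_cells)
    perm = rng.permutation(n_cells)
    group_of_cell = np.zeros(n_cells, dtype=int)  # 0 = no group
    group_names: dict[int, str] = {}
    pos = 0
    for gi, (p, cnt) in enumerate(zip(ordered, counts), start=1):
        group_names[gi] = p.name
        group_of_cell[perm[pos:pos + cnt]] = gi
        pos += cnt

    program_cells: dict[str, np.ndarray] = {}
    for p in config.programs:
        if p.overlap_with:
            mask = np.zeros(n_cells, dtype=bool)
            for o in p.overlap_with:
                gidx = next(g for g, nm in group_names.items() if nm == o)
                mask |= group_of_cell == gidx
            program_cells[p.name] = mask
        else:
            gidx = next(g for g, nm in group_names.items() if nm == p.name)
            program_cells[p.name] = group_of_cell == gidx

    rare_carriers: dict[str, set[str]] = {}
    for p in config.rare_programs:
        n_carrier = int(round(p.cell_fraction * n_cells))
        chosen = rng.choice(n_cells, size=n_carrier, replace=False)
        mask = np.zeros(n_cells, dtype=bool)
        mask[chosen] = True
        program_cells[p.name] = mask
        rare_carriers[p.name] = {cell_ids[i] for i in np.flatnonzero(mask)}

    qc_fail_idx = rng.choice(n_cells, size=config.n_qc_fail, replace=False)

    # --- annotation (round-robin chromosomes, increasing starts) --------
    chrom_of_gene = [f"chr{(i % config.n_chromosomes) + 1}" for i in range(n_genes)]
    start_of_gene = [(i // config.n_chromosomes) * 100_000 for i in range(n_genes)]
    annotation = GeneAnnotation(pd.DataFrame({
        "gene_id": gene_ids,
        "chromosome": chrom_of_gene,
        "start": start_of_gene,
    }))

    # --- latent log expression ------------------------------------------
    # gene baselines come from their own seed so the same gene id keeps its
    # characteristic expression level across cultures and replicates
    rng_genes = np.random.default_rng(config.gene_seed)
    mu = rng_genes.normal(config.base_log_mean, config.base_log_sd, size=n_genes)
    # planted marker genes are detectably expressed (like curated signature
    # genes): their base means are floored at the population mean
    for p in all_programs:
        for g in gene_programs[p.name]:
            i = gene_index[g]
            mu[i] = max(mu[i], config.base_log_mean)
    for hk in HOUSEKEEPING_GENES:
        mu[gene_index[hk]] = config.housekeeping_log_mean
    L = mu[:, None] + rng.normal(0.0, config.noise_sigma, size=(n_genes, n_cells))
    for p in all_programs:
        rows = [gene_index[g] for g in gene_programs[p.name]]
        carriers = np.flatnonzero(program_cells[p.name])
        # program activity varies continuously across carrier cells
        activity = np.exp(rng.normal(0.0, config.activity_sigma, size=carriers.size))
        L[np.ix_(rows, carriers)] += p.effect * activity[None, :]

    cnv_carriers: dict[str, set[str]] = {}
    clone_cells: dict[str, np.ndarray] = {}
    chrom_arr = np.array(chrom_of_gene)
    for ev in config.cnv_events:
        if ev.clone is not None and ev.clone in clone_cells:
            chosen = clone_cells[ev.clone]
        else:
            n_carrier = int(round(ev.cell_fraction * n_cells))
            chosen = rng.choice(n_cells, size=n_carrier, replace=False)
            if ev.clone is not None:
                clone_cells[ev.clone] = chosen
        rows = np.flatnonzero(chrom_arr == ev.chromosome)
        if rows.size == 0:
            raise ConfigurationError(f"CNV event on unknown chromosome {ev.chromosome}")
        L[np.ix_(rows, chosen)] += ev.log2_shift * np.log(2.0)
        cnv_carriers[ev.chromosome] = {cell_ids[i] for i in chosen}

    # --- emission --------------------------------------------------------
    lib = np.exp(rng.normal(0.0, config.library_size_sigma, size=n_cells))
    values = np.exp(L) * lib[None, :]
    if config.dropout_rate > 0:
        p_drop = np.minimum(1.0, config.dropout_rate * np.exp(-L))
        keep = rng.random(size=L.shape) >= p_drop
        for hk in HOUSEKEEPING_GENES:  # housekeeping never drops out
            keep[gene_index[hk], :] = True
        values = values * keep
    for hk in HOUSEKEEPING_GENES:
        values[gene_index[hk], qc_fail_idx] = 0.0

    E = ExpressionMatrix(values, gene_ids, cell_ids)
    truth = GroundTruth(
        cell_groups={c: int(g) for c, g in zip(cell_ids, group_of_cell)},
        group_names=group_names,
        rare_carriers=rare_carriers,
        gene_programs=gene_programs,
        cnv_carriers=cnv_carriers,
        qc_fail_cells=[cell_ids[i] for i in sorted(qc_fail_idx)],
        mu_g={g: float(m) for g, m in zip(gene_ids, mu)},
        library_factors={c: float(l) for c, l in zip(cell_ids, lib)},
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        E.to_frame().to_csv(out / "matrix.tsv", sep="\t", index_label="gene_id")
        annotation.table.to_csv(out / "annotation.tsv", sep="\t", index=False)
        write_gmt(truth.to_gene_sets(), out / "truth_sets.gmt", description="planted")
        labels = pd.DataFrame({
            "cell_id": cell_ids,
            "group": [truth.cell_groups[c] for c in cell_ids],
            "group_name": [group_names.get(truth.cell_groups[c], "none") for c in cell_ids],
            "qc_fail": [c in truth.qc_fail_cells for c in cell_ids],
            **{
                f"rare_{name}": [c in carriers for c in cell_ids]
                for name, carriers in rare_carriers.items()
            },
        })
        labels.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
        logger.info("synthetic culture written to %s", out)
    return E, annotation, truth


# ---------------------------------------------------------------------------
# Presets emulating the three melanoma short-term cultures

_PRESET_SEEDS = {"wtwt": 2016, "wtwt_replicate": 2017, "mutwt": 2018, "wtmut": 2019}

ABC_ALDH_SUBSETS = (("ABC_like", 16), ("ALDH_like", 8))


def preset(name: str, full_scale: bool = False) -> SyntheticConfig:
    """Named configurations mirroring the study's culture compositions.

    - ``wtwt``: BRAF/NRAS wild type culture — proliferation 45%, a
      pigmentation/MITF-like group 28%, stroma 27%; an oxidative-
      phosphorylation module shared by the first two groups; rare
      ABC/ALDH (10%, 16+8 marker genes) and KDM5B-like (7%)
      subpopulations; 4 of 96 chambers fail housekeeping QC.
    - ``wtwt_replicate``: as wtwt but proliferation 46% and a new seed.
    - ``mutwt``: BRAF-mutant culture — proliferation 30% and clonal
      copy-number gains on chr11, chr8, chr5 and chr19.
    - ``wtmut``: NRAS-mutant culture — proliferation 36% with a dominant
      stromal/AXL-like program.

    ``full_scale`` scales gene count to the ~15,000 of a real run.
    """
    common = dict(
        n_genes=15000 if full_scale else 2000,
        n_cells=96,
        n_qc_fail=4,
    )
    rare_abc = ProgramSpec("ABC_ALDH", n_genes=24, cell_fraction=0.10,
                           subsets=ABC_ALDH_SUBSETS)
    rare_kdm5b = ProgramSpec("KDM5B", n_genes=20, cell_fraction=0.07)
    if name == "wtwt" or name == "wtwt_replicate":
        prolif = 0.46 if name == "wtwt_replicate" else 0.45
        pigment = 1.0 - prolif - 0.27
        return SyntheticConfig(
            programs=[
                ProgramSpec("proliferation", 120, prolif),
                ProgramSpec("pigmentation", 120, round(pigment, 6)),
                ProgramSpec("stroma", 120, 0.27),
                ProgramSpec("oxphos", 120, 0.0,
                            overlap_with=("proliferation", "pigmentation")),
            ],
            rare_programs=[rare_abc, rare_kdm5b],
            seed=_PRESET_SEEDS[name],
            **common,
        )
    if name == "mutwt":
        return SyntheticConfig(
            programs=[
                ProgramSpec("proliferation", 120, 0.30),
                ProgramSpec("mito_exosome", 120, 0.40),
                ProgramSpec("melanocyte_active", 120, 0.30),
            ],
            rare_programs=[replace(rare_abc, cell_fraction=0.30)],
            cnv_events=[
                CNVEvent("chr11", 0.6, 1.0, clone="cnv_clone"),
                CNVEvent("chr8", 0.6, 1.0, clone="cnv_clone"),
                CNVEvent("chr5", 0.6, 0.8, clone="cnv_clone"),
                CNVEvent("chr19", 0.6, 0.8, clone="cnv_clone"),
            ],
            seed=_PRESET_SEEDS[name],
            **common,
        )
    if name == "wtmut":
        return SyntheticConfig(
            programs=[
                ProgramSpec("stroma_axl", 120, 0.45),
                ProgramSpec("proliferation", 120, 0.36),
                ProgramSpec("oxphos_pigment", 120, 0.19),
            ],
            rare_programs=[replace(rare_abc, cell_fraction=0.30)],
            seed=_PRESET_SEEDS[name],
            **common,
        )
    raise ConfigurationError(
        f"unknown preset {name!r}; available: {sorted(_PRESET_SEEDS)}"
    )
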