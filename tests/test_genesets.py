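import math

import numpy as np
import pytest

from somcell import (
    GeneSet,
    NormalizedMatrix,
    fisher_enrichment,
    flag_cells_by_gsz,
    geneset_map,
    gsz_profile,
    normalize,
    read_gmt,
    write_gmt,
)
from somcell.errors import ParseError, ValidationError
from somcell.genesets import GSZProfile
from somcell.som import SOMModel
from somcell.synthetic import generate, preset


def hypergeom_right_tail(a, spot, set_size, universe):
    """Exhaustive enumeration oracle for P(X >= a)."""
    total = 0.0
    for j in range(a, min(spot, set_size) + 1):
        total += (
            math.comb(set_size, j)
            * math.comb(universe - set_size, spot - j)
            / math.comb(universe, spot)
        )
    return total


class TestReadGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tg1\tg2\n")
        sets = read_gmt(p)
        assert len(sets) == 1
        assert sets[0].name == "S1"
        assert sets[0].gene_ids == {"g1", "g2"}

    def test_duplicates_within_line_deduplicated(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\td\tg1\tg1\tg2\n")
        assert len(read_gmt(p)[0]) == 2

    def test_three_line_file_matches_manual_parse(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("A\t.\tx\ty\nB\t.\tz\nC\t.\tx\tz\tw\n")
        sets = {s.name: s.gene_ids for s in read_gmt(p)}
        assert sets == {"A": {"x", "y"}, "B": {"z"}, "C": {"x", "z", "w"}}

    def test_empty_member_list_names_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("A\t.\tx\nB\t.\n")
        with pytest.raises(ParseError, match=":2"):
            read_gmt(p)

    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("S", frozenset({"a", "b", "c"}))]
        write_gmt(sets, tmp_path / "o.gmt")
        back = read_gmt(tmp_path / "o.gmt")
        assert back[0].gene_ids == sets[0].gene_ids


class TestFisherEnrichment:
    def test_perfect_overlap_small_universe(self):
        # universe 20, set 5, spot 5, overlap 5 -> p = 1 / C(20, 5)
        universe = {f"g{i}" for i in range(20)}
        five = {f"g{i}" for i in range(5)}
        res = fisher_enrichment(five, GeneSet("s", frozenset(five)), universe)
        assert res.p == pytest.approx(1.0 / math.comb(20, 5), rel=1e-12)
        assert (res.a, res.b, res.c, res.d) == (5, 0, 0, 15)

    def test_zero_overlap_right_tail_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        spot = {f"g{i}" for i in range(3)}
        gs = GeneSet("s", frozenset({f"g{i}" for i in range(5, 9)}))
        assert fisher_enrichment(spot, gs, universe).p == pytest.approx(1.0)

    def test_degenerate_spot_equals_universe(self):
        u = {f"g{i}" for i in range(8)}
        res = fisher_enrichment(u, GeneSet("s", frozenset(u)), u)
        assert res.p == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(50):
            M = int(rng.integers(5, 26))
            universe = {f"g{i}" for i in range(M)}
            spot = set(rng.choice(sorted(universe), size=int(rng.integers(1, M)), replace=False))
            gs = set(rng.choice(sorted(universe), size=int(rng.integers(1, M)), replace=False))
            res = fisher_enrichment(spot, GeneSet("s", frozenset(gs)), universe)
            oracle = hypergeom_right_tail(len(spot & gs), len(spot), len(gs), M)
            assert abs(res.p - oracle) < 1e-12

    def test_odds_ratio_continuity_correction(self):
        u = {f"g{i}" for i in range(10)}
        res = fisher_enrichment(
            {"g0", "g1"}, GeneSet("s", frozenset({"g0", "g1"})), u
        )
        assert res.b == 0 and res.c == 0
        assert res.odds_ratio == pytest.approx((2.5 * 8.5) / (0.5 * 0.5))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            fisher_enrichment(set(), GeneSet("s", frozenset({"a"})), set())


class TestGSZ:
    def test_whole_matrix_set_scores_near_zero(self):
        cfg = preset("wtwt")
        E, _, _ = generate(cfg)
        N = normalize(E)
        prof = gsz_profile(N, GeneSet("all", frozenset(N.gene_ids)))
        assert np.abs(prof.scores).max() <= 0.1

    def test_numerator_linear_in_set_expression(self, rng):
        X = rng.normal(size=(30, 8))
        genes = [f"g{i}" for i in range(30)]
        N = NormalizedMatrix(X, genes, [f"c{j}" for j in range(8)])
        gs = GeneSet("s", frozenset(genes[:6]))
        lam = 10.0
        p1 = gsz_profile(N, gs, lam)
        X2 = X.copy()
        X2[:6, :] *= 2.0
        p2 = gsz_profile(NormalizedMatrix(X2, genes, N.cell_ids), gs, lam)

        def numerator(prof, values):
            n = 6
            var_cell = values.var(axis=0)
            var_glob = values.var()
            shrunk = (n * var_cell + lam * var_glob) / (n + lam)
            return prof.scores * np.sqrt(n * shrunk)

        np.testing.assert_allclose(numerator(p2, X2), 2 * numerator(p1, X), atol=1e-9)

    def test_planted_program_separates_carriers(self):
        cfg = preset("wtwt")
        E, _, truth = generate(cfg)
        N = normalize(E)
        gs = GeneSet("abc", frozenset(truth.gene_programs["ABC_ALDH"]))
        prof = gsz_profile(N, gs)
        carriers = np.array([c in truth.rare_carriers["ABC_ALDH"] for c in N.cell_ids])
        assert prof.scores[carriers].mean() - prof.scores[~carriers].mean() > 3.0

    def test_planted_set_beats_permutation_null(self, rng):
        cfg = preset("wtwt")
        E, _, truth = generate(cfg)
        N = normalize(E)
        gs = GeneSet("abc", frozenset(truth.gene_programs["ABC_ALDH"]))
        prof = gsz_profile(N, gs)
        carriers = np.array([c in truth.rare_carriers["ABC_ALDH"] for c in N.cell_ids])
        observed = prof.scores[carriers].mean()
        null = []
        for _ in range(100):
            perm = rng.permutation(len(carriers))
            null.append(prof.scores[perm[: carriers.sum()]].mean())
        assert observed > np.quantile(null, 0.99)

    def test_absent_set_rejected_with_missing_genes(self):
        N = NormalizedMatrix(np.zeros((3, 3)), list("abc"), list("xyz"))
        with pytest.raises(ValidationError, match="absent|no gene"):
            gsz_profile(N, GeneSet("s", frozenset({"q1", "q2"})))


class TestFlagCells:
    def test_bimodal_scores_flag_exactly_the_outliers(self, rng):
        bulk = rng.normal(0.0, 1.0, 80)
        carriers = rng.normal(12.0, 1.0, 9)
        scores = np.concatenate([bulk, carriers])
        prof = GSZProfile("s", scores, [f"c{i}" for i in range(89)])
        mask, thr = flag_cells_by_gsz(prof)
        assert mask.sum() == 9
        assert set(np.flatnonzero(mask)) == set(range(80, 89))

    def test_unimodal_scores_flag_nothing_extreme(self, rng):
        scores = rng.normal(size=200)
        prof = GSZProfile("s", scores, [f"c{i}" for i in range(200)])
        mask, _ = flag_cells_by_gsz(prof)
        assert mask.mean() < 0.02


class TestGeneSetMap:
    def test_single_gene_set(self):
        M = SOMModel(3, 3, np.zeros((9, 2)), {"a": 4, "b": 0}, ["c0", "c1"])
        gm = geneset_map(M, GeneSet("s", frozenset({"a"})))
        assert gm.total == 1
        assert gm.counts[1, 1] == 1

    def test_all_genes_conserved(self):
        g2u = {f"g{i}": i % 9 for i in range(30)}
        M = SOMModel(3, 3, np.zeros((9, 2)), g2u, ["c0", "c1"])
        gm = geneset_map(M, GeneSet("s", frozenset(g2u)))
        assert gm.total == 30

    def test_absent_genes_not_counted(self):
        M = SOMModel(2, 2, np.zeros((4, 2)), {"a": 0}, ["c0", "c1"])
        gm = geneset_map(M, GeneSet("s", frozenset({"a", "zz"})))
        assert gm.total == 1

    def test_planted_program_mass_in_matching_spot(self):
        # >= 60% of the proliferation set's mass falls in its own spot units
        import somcell as sc

        cfg = preset("wtwt")
        E, _, truth = generate(cfg)
        res = sc.analyze(E, params=sc.PipelineParams(seed=cfg.seed))
        gs = GeneSet("prolif", frozenset(truth.gene_programs["proliferation"]))
        spot = sc.identify_program_spot(res, gs)
        gm = geneset_map(res.model, gs)
        in_spot = sum(gm.counts[r, c] for r, c in spot.unit_indices)
        assert in_spot / gm.total >= 0.6
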