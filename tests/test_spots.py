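import numpy as np
import pytest

from somcell import (
    NormalizedMatrix,
    attach_spot_genes,
    detect_spots,
    spots_per_cell,
    summary_overexpression_map,
    train_som,
)
from somcell.errors import ValidationError
from somcell.som import Portrait, SOMModel
from somcell.spots import SpotModule


def _flood_fill_components(mask):
    """Brute-force 8-connected component labeling oracle."""
    comps = []
    seen = np.zeros_like(mask, dtype=bool)
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, comp = [(r0, c0)], set()
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps


class TestSummaryMap:
    @pytest.fixture
    def toy_model(self):
        cb = np.array([[0.0, 1.0, 2.0], [5.0, 5.0, 5.0], [-1.0, 0.0, 4.0], [2.0, 2.0, 0.0]])
        return SOMModel(2, 2, cb, {"g0": 0, "g1": 1}, ["c0", "c1", "c2"])

    def test_q1_gives_per_unit_maxima(self, toy_model):
        P = summary_overexpression_map(toy_model, q=1.0)
        np.testing.assert_array_equal(P.values.reshape(-1), [2.0, 5.0, 4.0, 2.0])

    def test_constant_codebook_gives_constant_map(self):
        M = SOMModel(2, 2, np.full((4, 3), 1.5), {"g": 0}, list("abc"))
        P = summary_overexpression_map(M, q=0.98)
        assert np.ptp(P.values) == 0.0

    def test_matches_per_row_quantile_oracle(self, toy_model):
        P = summary_overexpression_map(toy_model, q=0.5)
        expected = [np.quantile(row, 0.5) for row in toy_model.codebook]
        np.testing.assert_allclose(P.values.reshape(-1), expected)

    @pytest.mark.parametrize("q", [0.0, -0.1, 1.5])
    def test_invalid_quantile_rejected(self, toy_model, q):
        with pytest.raises(ValidationError):
            summary_overexpression_map(toy_model, q=q)


class TestDetectSpots:
    def test_single_plateau(self):
        V = np.zeros((10, 10))
        V[2:5, 3:6] = 1.0
        spots = detect_spots(Portrait(V, "t"), threshold_quantile=0.92, min_units=5)
        assert len(spots) == 1
        assert spots[0].n_units == 9
        assert spots[0].label == "A"

    def test_two_plateaus_and_bridge_merge(self):
        V = np.zeros((12, 12))
        V[1:4, 1:4] = 1.0
        V[8:11, 8:11] = 0.8
        spots = detect_spots(Portrait(V, "t"), threshold_quantile=0.9, min_units=5)
        assert len(spots) == 2
        assert spots[0].peak_value == 1.0  # A = higher peak
        # fill the diagonal gap -> single component (flood-fill oracle agrees)
        for i in range(4, 8):
            V[i, i] = 0.9
        merged = detect_spots(Portrait(V, "t"), threshold_quantile=0.9, min_units=5)
        assert len(merged) == 1
        oracle = _flood_fill_components(V >= np.quantile(V, 0.9))
        assert len([c for c in oracle if len(c) >= 5]) == 1

    def test_uniform_portrait_is_one_grid_spot(self):
        V = np.full((6, 6), 2.0)
        spots = detect_spots(Portrait(V, "t"), threshold_quantile=0.9, min_units=5)
        assert len(spots) == 1
        assert spots[0].n_units == 36

    def test_no_large_component_gives_empty_list(self):
        V = np.zeros((10, 10))
        V[0, 0] = 1.0
        assert detect_spots(Portrait(V, "t"), threshold_quantile=0.99, min_units=5) == []

    def test_spots_disjoint_and_connected(self, rng):
        V = rng.normal(size=(20, 20))
        spots = detect_spots(Portrait(V, "t"), threshold_quantile=0.7, min_units=3)
        all_units = [u for s in spots for u in s.unit_indices]
        assert len(all_units) == len(set(all_units))
        for s in spots:
            mask = np.zeros((20, 20), dtype=bool)
            for r, c in s.unit_indices:
                mask[r, c] = True
            assert len(_flood_fill_components(mask)) == 1

    def test_dilation_preserves_disjointness_and_connectivity(self):
        V = np.zeros((12, 12))
        V[2:5, 2:5] = 1.0
        V[2:5, 7:10] = 0.9
        spots = detect_spots(Portrait(V, "t"), threshold_quantile=0.9, min_units=5, dilate=1)
        assert len(spots) == 2
        units_a, units_b = spots[0].unit_indices, spots[1].unit_indices
        assert units_a.isdisjoint(units_b)
        # contested middle column (5,6 dilate into col 5/6 overlap region)
        assert all(len(_flood_fill_components(
            np.isin(np.arange(144).reshape(12, 12),
                    [r * 12 + c for r, c in s.unit_indices]))) == 1 for s in spots)

    def test_refinement_splits_dissimilar_cores_only(self):
        # one foreground blob holding two high cores with uncorrelated profiles
        V = np.zeros((10, 10))
        V[2:7, 2:4] = 0.8
        V[2:4, 2:4] = 2.0  # core 1
        V[5:7, 2:4] = 1.9  # core 2
        cb = np.zeros((100, 6))
        prof1, prof2 = np.array([1.0, 1, 1, -1, -1, -1]), np.array([-1.0, -1, 1, 1, 1, -1])
        for r in range(2, 4):
            for c in range(2, 4):
                cb[r * 10 + c] = prof1
        for r in range(5, 7):
            for c in range(2, 4):
                cb[r * 10 + c] = prof2
        split = detect_spots(
            Portrait(V, "t"), threshold_quantile=0.9, min_units=2,
            refine_quantile=0.0, codebook=cb, core_min_units=3,
        )
        assert len(split) == 2
        # identical core profiles -> treated as one module, no split
        for r in range(5, 7):
            for c in range(2, 4):
                cb[r * 10 + c] = prof1
        kept = detect_spots(
            Portrait(V, "t"), threshold_quantile=0.9, min_units=2,
            refine_quantile=0.0, codebook=cb, core_min_units=3,
        )
        assert len(kept) == 1


class TestAttachSpotGenes:
    @pytest.fixture
    def model_and_norm(self, rng):
        n_cells = 6
        profile = np.array([2.0, 1.0, 0.0, -1.0, -2.0, 0.0])
        genes, rows = [], []
        genes.append("match")
        rows.append(profile.copy())
        genes.append("anti")
        rows.append(-profile)
        for i in range(8):
            genes.append(f"r{i}")
            rows.append(rng.normal(size=n_cells))
        X = np.array(rows)
        N = NormalizedMatrix(X, genes, [f"c{j}" for j in range(n_cells)])
        # all genes map into a 2x2 spot on a 4x4 grid; spot profile == profile
        cb = np.tile(profile, (16, 1)) * 0.0
        for u in (0, 1, 4, 5):
            cb[u] = profile
        g2u = {g: (0, 1, 4, 5)[i % 4] for i, g in enumerate(genes)}
        M = SOMModel(4, 4, cb, g2u, N.cell_ids)
        return M, N

    def test_ranking_matches_pearson_oracle(self, model_and_norm):
        M, N = model_and_norm
        spot = SpotModule("A", {(0, 0), (0, 1), (1, 0), (1, 1)})
        attach_spot_genes(M, N, spot)
        assert [g for g, _ in spot.member_genes][0] == "match"
        assert spot.member_genes[0][1] == pytest.approx(1.0)
        assert spot.member_genes[-1][0] == "anti"
        assert spot.member_genes[-1][1] == pytest.approx(-1.0)
        rs = dict(spot.member_genes)
        for g, r in rs.items():
            expected = np.corrcoef(
                N.values[N.gene_ids.index(g)], spot.profile
            )[0, 1]
            assert r == pytest.approx(expected, abs=1e-12)
        rvals = [r for _, r in spot.member_genes]
        assert rvals == sorted(rvals, reverse=True)

    def test_empty_spot_logs_and_returns_empty(self, model_and_norm, caplog):
        M, N = model_and_norm
        spot = SpotModule("Z", {(3, 3)})
        attach_spot_genes(M, N, spot)
        assert spot.member_genes == []

    def test_out_of_grid_units_rejected(self, model_and_norm):
        M, N = model_and_norm
        with pytest.raises(ValidationError):
            attach_spot_genes(M, N, SpotModule("X", {(9, 9)}))


class TestSpotsPerCell:
    def test_counts_match_brute_force(self, two_program_normalized):
        N = two_program_normalized
        M = train_som(N, 8, 8, epochs=12, seed=4)
        S = summary_overexpression_map(M, q=0.9)
        spots = detect_spots(S, threshold_quantile=0.75, min_units=3)
        assert len(spots) >= 2
        dist = spots_per_cell(M, spots, cell_threshold_quantile=0.9)
        for idx, cell in enumerate(M.cell_ids):
            portrait = M.codebook[:, idx]
            thr = np.quantile(portrait, 0.9)
            expected = 0
            for s in spots:
                units = [r * 8 + c for r, c in s.unit_indices]
                expected += portrait[units].mean() > thr
            assert dist.counts[cell] == expected

    def test_constant_portrait_has_zero_spots_on(self):
        cb = np.ones((16, 2))
        M = SOMModel(4, 4, cb, {"g": 0}, ["c0", "c1"])
        dist = spots_per_cell(M, [SpotModule("A", {(0, 0), (0, 1)})])
        assert all(v == 0 for v in dist.counts.values())

    def test_requires_spots(self, two_program_normalized):
        M = train_som(two_program_normalized, 6, 6, epochs=6, seed=0)
        with pytest.raises(ValidationError):
            spots_per_cell(M, [])
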