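import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somcell import (
    ExpressionMatrix,
    filter_invariant_genes,
    normalize,
    qc_filter_cells,
    read_expression,
)
from somcell.errors import (
    ConfigurationError,
    EmptyResultError,
    ValidationError,
)
from somcell.preprocess import quantile_normalize

from conftest import brute_force_quantile_normalize


class TestReadExpression:
    def test_tsv_identity_parse(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\tc1\tc2\ng1\t1\t0\ng2\t2\t3\n")
        E = read_expression(p)
        assert E.gene_ids == ["g1", "g2"]
        assert E.cell_ids == ["c1", "c2"]
        np.testing.assert_array_equal(E.values, [[1, 0], [2, 3]])

    def test_triplet_densification(self, tmp_path):
        # single entry (g2, c1, 5) over a declared 2x2 shape -> [[0,0],[5,0]]
        p = tmp_path / "m.mtx"
        p.write_text("%%MatrixMarket matrix coordinate real general\n2 2 1\n2 1 5\n")
        (tmp_path / "m.rows.txt").write_text("g1\ng2\n")
        (tmp_path / "m.cols.txt").write_text("c1\nc2\n")
        E = read_expression(p, format="mtx-triplet")
        np.testing.assert_array_equal(E.values, [[0, 0], [5, 0]])

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\tc1\ng1\t1\ng1\t2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_expression(p)

    def test_missing_sidecar(self, tmp_path):
        p = tmp_path / "m.mtx"
        p.write_text("%%MatrixMarket matrix coordinate real general\n1 1 1\n1 1 2\n")
        with pytest.raises(FileNotFoundError):
            read_expression(p, format="mtx-triplet")

    @pytest.mark.parametrize(
        "values,err",
        [([[1.0, -0.5]], "nonnegative"), ([[1.0, np.nan]], "finite")],
    )
    def test_matrix_invariants(self, values, err):
        with pytest.raises(ValidationError, match=err):
            ExpressionMatrix(np.array(values), ["g1"], ["c1", "c2"])


class TestQCFilter:
    def _matrix(self, actb, gapdh, extra=None):
        rows = [actb, gapdh] + (extra or [[1.0] * len(actb)])
        genes = ["ACTB", "GAPDH"] + [f"G{i}" for i in range(len(rows) - 2)]
        cells = [f"C{i}" for i in range(len(actb))]
        return ExpressionMatrix(np.array(rows, dtype=float), genes, cells)

    def test_double_zero_removed_single_positive_retained(self):
        # "express" means strictly > 0: ACTB=0 & GAPDH=0 removed, GAPDH=0.1 kept
        E = self._matrix([0.0, 0.0, 5.0], [0.0, 0.1, 0.0])
        F, report = qc_filter_cells(E)
        assert report.removed_cell_ids == ["C0"]
        assert F.cell_ids == ["C1", "C2"]
        assert F.gene_ids == E.gene_ids

    def test_all_expressing_is_noop(self):
        E = self._matrix([1.0, 2.0], [0.0, 0.0])
        F, report = qc_filter_cells(E)
        assert report.n_retained == report.n_input_cells == 2

    def test_planted_failures_match_brute_force(self, rng):
        n_cells = 40
        actb = rng.exponential(2.0, n_cells)
        gapdh = rng.exponential(2.0, n_cells)
        fail = rng.choice(n_cells, size=7, replace=False)
        actb[fail] = 0.0
        gapdh[fail] = 0.0
        E = self._matrix(list(actb), list(gapdh))
        _, report = qc_filter_cells(E)
        expected = [
            E.cell_ids[j] for j in range(n_cells) if actb[j] == 0 and gapdh[j] == 0
        ]
        assert sorted(report.removed_cell_ids) == sorted(expected)
        assert len(report.removed_cell_ids) == 7

    def test_idempotent(self):
        E = self._matrix([0.0, 1.0, 0.0], [0.0, 0.0, 2.0])
        F1, _ = qc_filter_cells(E)
        F2, r2 = qc_filter_cells(F1)
        assert F2.cell_ids == F1.cell_ids
        assert r2.removed_cell_ids == []

    def test_no_housekeeping_gene_is_config_error(self):
        E = ExpressionMatrix(np.ones((2, 2)), ["G1", "G2"], ["C0", "C1"])
        with pytest.raises(ConfigurationError):
            qc_filter_cells(E)

    def test_all_cells_removed_is_explicit_error(self):
        E = self._matrix([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(EmptyResultError):
            qc_filter_cells(E)


class TestNormalize:
    def test_three_by_three_matches_sort_average_oracle(self, rng):
        X = rng.permutation(np.arange(9.0)).reshape(3, 3)
        E = ExpressionMatrix(X, ["g1", "g2", "g3"], ["c1", "c2", "c3"])
        N = normalize(E, log_transform=False)
        expected = brute_force_quantile_normalize(X)
        expected -= expected.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(N.values, expected, atol=1e-12)

    def test_identical_multisets_align_after_qn(self):
        # two cells with the same values in permuted gene order
        X = np.array([[1.0, 3.0], [2.0, 1.0], [3.0, 2.0]])
        Q = quantile_normalize(X)
        np.testing.assert_allclose(np.sort(Q[:, 0]), np.sort(Q[:, 1]))

    def test_ties_receive_mean_of_rank_means(self):
        X = np.array([[1.0, 5.0], [1.0, 2.0], [4.0, 8.0]])
        Q = quantile_normalize(X)
        rank_means = np.sort(X, axis=0).mean(axis=1)
        # column 0 has a tie on its two lowest values
        assert Q[0, 0] == Q[1, 0] == pytest.approx(rank_means[:2].mean())
        np.testing.assert_allclose(np.sort(Q[:, 1]), rank_means)

    def test_gene_rows_center_to_zero(self, small_expression):
        N = normalize(small_expression)
        np.testing.assert_allclose(N.values.sum(axis=1), 0.0, atol=1e-9)

    def test_constant_matrix_gives_zeros(self):
        E = ExpressionMatrix(np.full((3, 4), 7.0), list("abc"), list("wxyz"))
        N = normalize(E)
        np.testing.assert_allclose(N.values, 0.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_cell_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = np.exp(rng.normal(size=(12, 6)))
        E = ExpressionMatrix(X, [f"g{i}" for i in range(12)], [f"c{j}" for j in range(6)])
        perm = rng.permutation(6)
        Ep = ExpressionMatrix(X[:, perm], E.gene_ids, [E.cell_ids[j] for j in perm])
        N, Np = normalize(E), normalize(Ep)
        np.testing.assert_allclose(Np.values, N.values[:, perm], atol=1e-12)

    def test_sorted_columns_identical_before_centering(self, small_expression):
        Q = quantile_normalize(np.log10(small_expression.values + 1))
        ref = np.sort(Q[:, 0])
        for j in range(1, Q.shape[1]):
            np.testing.assert_allclose(np.sort(Q[:, j]), ref, atol=1e-12)

    def test_too_few_cells_rejected(self):
        E = ExpressionMatrix(np.ones((3, 1)), list("abc"), ["c"])
        with pytest.raises(ValidationError):
            normalize(E)


class TestFilterInvariantGenes:
    def test_constant_gene_removed(self, small_expression):
        N = normalize(small_expression)
        N.values[3, :] = 0.0
        out = filter_invariant_genes(N, min_sd=0.0)
        assert small_expression.gene_ids[3] not in out.gene_ids
        assert out.n_genes == N.n_genes - 1

    def test_negative_threshold_is_vacuous(self, small_expression):
        N = normalize(small_expression)
        out = filter_invariant_genes(N, min_sd=-1.0)
        assert out.gene_ids == N.gene_ids

    def test_matches_per_row_sd_oracle(self, rng):
        from somcell import NormalizedMatrix

        X = rng.normal(size=(100, 10))
        X[rng.choice(100, 20, replace=False), :] = 0.3  # constant rows
        N = NormalizedMatrix(X, [f"g{i}" for i in range(100)], [f"c{j}" for j in range(10)])
        out = filter_invariant_genes(N, min_sd=0.05)
        expected = [g for g, row in zip(N.gene_ids, X) if row.std() > 0.05]
        assert out.gene_ids == expected

    def test_all_removed_is_error(self):
        from somcell import NormalizedMatrix

        N = NormalizedMatrix(np.zeros((3, 4)), list("abc"), list("wxyz"))
        with pytest.raises(EmptyResultError):
            filter_invariant_genes(N)
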