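import numpy as np
import pytest

from somcell import ExpressionMatrix, NormalizedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression(rng):
    """30 genes x 8 cells of log-normal FPKM-like values incl. housekeeping."""
    genes = ["ACTB", "GAPDH"] + [f"G{i:02d}" for i in range(28)]
    values = np.exp(rng.normal(0.5, 1.0, size=(30, 8)))
    return ExpressionMatrix(values, genes, [f"C{i}" for i in range(8)])


@pytest.fixture
def two_program_normalized(rng):
    """Two orthogonal gene programs: block structure over 12 cells.

    Genes 0-39 are high in cells 0-5, genes 40-79 in cells 6-11; a
    centered matrix with additive noise.
    """
    n_genes, n_cells = 80, 12
    X = rng.normal(0.0, 0.1, size=(n_genes, n_cells))
    X[:40, :6] += 1.0
    X[40:, 6:] += 1.0
    X -= X.mean(axis=1, keepdims=True)
    return NormalizedMatrix(
        X, [f"G{i:03d}" for i in range(n_genes)], [f"C{i:02d}" for i in range(n_cells)]
    )


def brute_force_quantile_normalize(X):
    """Independent sort/average oracle for rank-mean quantile normalization."""
    X = np.asarray(X, dtype=float)
    n_rows, n_cols = X.shape
    rank_means = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(n_cols):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        vals = np.empty(n_rows)
        i = 0
        while i < n_rows:
            k = i
            while k + 1 < n_rows and col[order[k + 1]] == col[order[i]]:
                k += 1
            vals[i : k + 1] = rank_means[i : k + 1].mean()
            i = k + 1
        out[order, j] = vals
    return out


def brute_force_silhouette(D, labels):
    """Per-item silhouette widths (b - a) / max(a, b) from a distance matrix."""
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            widths[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in same])
        b = np.inf
        for g in set(labels):
            if g == labels[i]:
                continue
            others = [j for j in range(n) if labels[j] == g]
            b = min(b, np.mean([D[i, j] for j in others]))
        widths[i] = (b - a) / max(a, b)
    return widths
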