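import numpy as np
import pytest

from coexstack.io_formats import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 features x 4 samples with two groups of two."""
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2", "s3", "s4"],
        rng.normal(size=(3, 4)),
        {"s1": "ctrl", "s2": "ctrl", "s3": "case", "s4": "case"},
    )


@pytest.fixture
def two_group_matrix() -> ExpressionMatrix:
    """50 features, 6 vs 6 samples, pure noise."""
    rng = np.random.default_rng(7)
    samples = [f"c{i}" for i in range(6)] + [f"t{i}" for i in range(6)]
    groups = {s: ("control" if s.startswith("c") else "case") for s in samples}
    return ExpressionMatrix([f"g{i}" for i in range(50)], samples,
                            rng.normal(size=(50, 12)), groups)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap, the independent oracle."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.empty_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a
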