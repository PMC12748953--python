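"""Shared fixtures: small seeded synthetic instances built at test time."""

import numpy as np
import pytest

from cisimc.core import Dictionary, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expression(rng):
    """A 4-protein x 6-cell nonnegative matrix with generic values."""
    values = rng.gamma(2.0, 1.0, size=(4, 6))
    return ExpressionMatrix(values, [f"p{i}" for i in range(4)], [f"c{i}" for i in range(6)])


def make_module_basis(p, d, seed):
    """Random nonnegative unit-column basis (p x d) without zero columns."""
    rng = np.random.default_rng(seed)
    U = np.abs(rng.normal(size=(p, d))) + 0.05
    return U / np.linalg.norm(U, axis=0)


def make_sparse_activity(d, n, k, seed, scale=1.0):
    """(d x n) nonnegative with at most k nonzeros per column."""
    rng = np.random.default_rng(seed)
    W = np.zeros((d, n))
    for j in range(n):
        nnz = int(rng.integers(1, k + 1))
        idx = rng.choice(d, size=nnz, replace=False)
        W[idx, j] = rng.gamma(2.0, scale, size=nnz)
    return W


@pytest.fixture
def block_structured_expression():
    """Two disjoint cell populations, each expressing a disjoint 3-protein block."""
    rng = np.random.default_rng(7)
    p, n_per = 6, 40
    u1 = np.array([1.0, 0.8, 0.6, 0, 0, 0])
    u2 = np.array([0, 0, 0, 0.5, 1.0, 0.9])
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    a1 = rng.gamma(3.0, 1.0, size=n_per)
    a2 = rng.gamma(3.0, 1.0, size=n_per)
    X = np.concatenate([np.outer(u1, a1), np.outer(u2, a2)], axis=1)
    em = ExpressionMatrix(
        X, [f"p{i}" for i in range(p)], [f"c{i}" for i in range(2 * n_per)]
    )
    truth = Dictionary(
        np.stack([u1, u2], axis=1), em.protein_ids, ["b1", "b2"]
    )
    return em, truth
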