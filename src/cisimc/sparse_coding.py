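"""Shared sparse solvers: error-constrained Lasso and fixed-sparsity OMP.

The decompression model needs the *sparsest* coefficient matrix ``W`` whose
reconstruction error stays inside a relative tolerance:

    min ||W||_1   s.t.   ||T - B W||_F^2 <= lda * ||T||_F^2

for a target ``T`` (q x n) and basis ``B`` (q x d).  No closed-form solver
exists for this constrained form, so it is reduced to the penalized
nonnegative Lasso and the penalty weight is found by bisection: the largest
penalty (hence sparsest solution) still satisfying the error constraint is
returned.  Columns (cells) may be partitioned into blocks by vector size,
each block receiving its own penalty.

OMP covers the complementary parameterization: instead of an error budget,
an explicit per-cell sparsity ``k`` bounds how many basis atoms may be
active.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, orthogonal_mp

from .core import ValidationError

__all__ = [
    "SparseDecodeConfig",
    "sparse_decode_lasso",
    "sparse_decode_omp",
    "InfeasibleDecodeWarning",
]

#: relative slack allowed on the error constraint (numerical tolerance)
TOL_SLACK = 1e-3


class InfeasibleDecodeWarning(UserWarning):
    """The error constraint could not be met even with a vanishing penalty."""


@dataclass
class SparseDecodeConfig:
    """Solver settings shared by the factorization and decompression stages.

    ``lda`` is the relative squared-error tolerance of the constrained Lasso
    (``ldaW`` when solving for module activities); ``k`` the OMP sparsity;
    ``num_blocks`` splits cells into equal-count vector-size quantile groups
    solved with group-specific penalties.
    """

    method: str = "lasso"
    lda: float = 0.02
    k: int = 4
    num_blocks: int = 1
    nonnegative: bool = True
    max_bisection_steps: int = 40

    def __post_init__(self) -> None:
        if self.method not in ("lasso", "omp"):
            raise ValidationError(f"method must be 'lasso' or 'omp', got {self.method!r}")
        if self.method == "lasso" and not self.lda > 0:
            raise ValidationError(f"lda must be positive, got {self.lda}")
        if self.method == "omp" and self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.num_blocks < 1:
            raise ValidationError(f"num_blocks must be >= 1, got {self.num_blocks}")
        if self.max_bisection_steps < 1:
            raise ValidationError("max_bisection_steps must be >= 1")


def _check_inputs(target, basis):
    target = np.asarray(target, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if target.ndim == 1:
        target = target[:, None]
    if target.ndim != 2 or basis.ndim != 2:
        raise ValidationError("target and basis must be 2-D matrices")
    if target.shape[0] != basis.shape[0]:
        raise ValidationError(
            f"target has {target.shape[0]} rows but basis has {basis.shape[0]}"
        )
    if not np.isfinite(target).all() or not np.isfinite(basis).all():
        raise ValidationError("target and basis must be finite")
    return target, basis


def _fit_lasso(basis: np.ndarray, tgt: np.ndarray, alpha: float, nonneg: bool) -> np.ndarray:
    model = Lasso(
        alpha=alpha,
        positive=nonneg,
        fit_intercept=False,
        max_iter=2000,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(basis, tgt)
    coef = model.coef_  # (n_targets, d) or (d,) for a single target
    if coef.ndim == 1:
        coef = coef[None, :]
    return coef.T


def _decode_block(
    basis: np.ndarray,
    tgt: np.ndarray,
    lda: float,
    nonneg: bool,
    max_steps: int,
) -> tuple[np.ndarray, bool]:
    """Bisection on the L1 penalty for one block of cells.

    Returns the sparsest iterate satisfying the constraint and a feasibility
    flag.  Infeasible targets fall back to the (sign-constrained)
    least-squares solution obtained at a vanishing penalty.
    """
    d = basis.shape[1]
    n = tgt.shape[1]
    tnorm2 = float((tgt**2).sum())
    if tnorm2 == 0.0:
        return np.zeros((d, n)), True
    bound = lda * tnorm2 * (1.0 + TOL_SLACK)
    q = basis.shape[0]
    alpha_max = float(np.abs(basis.T @ tgt).max()) / q
    if alpha_max == 0.0:
        # basis entirely orthogonal to target (or zero): only W = 0 possible
        return np.zeros((d, n)), tnorm2 <= bound
    alpha_lo = alpha_max * 1e-6

    def solve(alpha: float) -> tuple[np.ndarray, float]:
        W = _fit_lasso(basis, tgt, alpha, nonneg)
        err = float(((tgt - basis @ W) ** 2).sum())
        return W, err

    W_lo, err_lo = solve(alpha_lo)
    if err_lo > bound:
        return W_lo, False
    lo, hi = alpha_lo, alpha_max
    W_best = W_lo
    for _ in range(max_steps):
        if hi / lo <= 1.02:
            break
        mid = math.sqrt(lo * hi)
        W_mid, err_mid = solve(mid)
        if err_mid <= bound:
            lo, W_best = mid, W_mid
        else:
            hi = mid
    return W_best, True


def _block_partition(target: np.ndarray, num_blocks: int) -> list[np.ndarray]:
    """Split cell indices into vector-size (column L2 norm) quantile groups."""
    n = target.shape[1]
    num_blocks = min(num_blocks, n)
    order = np.argsort(np.linalg.norm(target, axis=0), kind="stable")
    return [np.sort(b) for b in np.array_split(order, num_blocks)]


def sparse_decode_lasso(
    target,
    basis,
    lda: float = 0.02,
    num_blocks: int = 1,
    nonnegative: bool = True,
    max_bisection_steps: int = 40,
    return_info: bool = False,
    warn_infeasible: bool = True,
):
    """Sparsest coefficients with relative squared error at most ``lda``.

    Solves ``min ||W||_1 s.t. ||target - basis @ W||_F^2 <= lda *
    ||target||_F^2`` (per block of cells when ``num_blocks > 1``) via
    bisection on the L1 penalty of a penalized (nonnegative) Lasso.  When
    the constraint is unattainable even at a vanishing penalty, the
    least-squares solution is returned and an
    :class:`InfeasibleDecodeWarning` is emitted.

    Returns the (d x n) coefficient matrix; with ``return_info=True`` also a
    dict with the per-block feasibility flags.
    """
    if not lda > 0:
        raise ValidationError(f"lda must be positive, got {lda}")
    if num_blocks < 1:
        raise ValidationError(f"num_blocks must be >= 1, got {num_blocks}")
    target, basis = _check_inputs(target, basis)
    d, n = basis.shape[1], target.shape[1]
    W = np.zeros((d, n))
    feasible: list[bool] = []
    for cols in _block_partition(target, num_blocks):
        Wb, ok = _decode_block(
            basis, target[:, cols], lda, nonnegative, max_bisection_steps
        )
        W[:, cols] = Wb
        feasible.append(ok)
    if not all(feasible) and warn_infeasible:
        warnings.warn(
            "error constraint infeasible for "
            f"{sum(not f for f in feasible)}/{len(feasible)} block(s); "
            "returning least-squares fallback",
            InfeasibleDecodeWarning,
            stacklevel=2,
        )
    if return_info:
        return W, {"feasible": feasible, "all_feasible": all(feasible)}
    return W


def sparse_decode_omp(
    target,
    basis,
    k: int,
    nonnegative: bool = True,
):
    """Greedy per-cell orthogonal matching pursuit with at most ``k`` atoms.

    Basis columns are L2-normalized for atom selection (coefficients are
    rescaled back), zero columns are never selected, and selection ties
    resolve to the lowest column index.  Negative coefficients are clipped
    to zero afterwards when ``nonnegative`` is set.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    target, basis = _check_inputs(target, basis)
    d = basis.shape[1]
    if k > d:
        raise ValidationError(f"k={k} exceeds the number of basis columns {d}")
    norms = np.linalg.norm(basis, axis=0)
    nonzero = norms > 0
    if not nonzero.any():
        return np.zeros((d, target.shape[1]))
    unit = basis[:, nonzero] / norms[nonzero]
    k_eff = min(k, int(nonzero.sum()), basis.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        coef = orthogonal_mp(unit, target, n_nonzero_coefs=k_eff)
    if coef.ndim == 1:
        coef = coef[:, None]
    W = np.zeros((d, target.shape[1]))
    W[nonzero, :] = coef / norms[nonzero][:, None]
    if nonnegative:
        np.maximum(W, 0.0, out=W)
    return W


def sparse_decode(target, basis, config: SparseDecodeConfig):
    """Dispatch to the configured solver."""
    if config.method == "lasso":
        return sparse_decode_lasso(
            target,
            basis,
            lda=config.lda,
            num_blocks=config.num_blocks,
            nonnegative=config.nonnegative,
            max_bisection_steps=config.max_bisection_steps,
        )
    return sparse_decode_omp(target, basis, k=config.k, nonnegative=config.nonnegative)
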