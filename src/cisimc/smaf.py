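"""Sparse Module Activity Factorization (SMAF).

SMAF decomposes training single-cell protein expression ``X`` (p x n) into a
dictionary of protein-expression modules ``U`` (p x d) and sparse per-cell
module activities ``W`` (d x n) so that ``X ~= U @ W`` with *both* factors
sparse: each module involves a few proteins, each cell activates a few
modules.  The algorithm alternates, starting from an NMF seed:

1. W-step: fix U, solve the error-constrained Lasso (tolerance ``ldaW``) or
   OMP (sparsity ``k``) for W.
2. U-step: fix W, solve the error-constrained Lasso (tolerance ``ldaU``) for
   U, row-wise through the same bisection machinery on the transposed
   problem.
3. Normalize every module column of U to unit L2 norm (activities are
   rescaled inversely so the product is preserved).

A fixed number of iterations is run (default 100); all-zero modules are
pruned once at the end, so the effective module count ``d`` can come out
well below the initial ``d0`` when tolerances are loose.

The defaults (``lasso``, ``ldaU = ldaW = 0.02``, one cell block, ``d0 = 80``)
are the finalized parameter set for learning immune/stromal marker modules
from imaging mass cytometry panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF
from sklearn.utils.validation import check_is_fitted

from .core import Dictionary, ExpressionMatrix, ModuleActivity, ValidationError
from .sparse_coding import sparse_decode_lasso, sparse_decode_omp

__all__ = ["SmafConfig", "SMAF", "nmf_init", "fit_smaf", "dictionary_stats"]


@dataclass
class SmafConfig:
    """Hyperparameters of the factorization.

    d0: initial number of modules before pruning (default 80).
    iterations: alternating rounds (default 100; no early stop by default).
    algorithm_for_W: 'lasso' (error tolerance ldaW) or 'omp' (sparsity k).
    ldaU / ldaW: relative squared-error tolerances of the U- and W-steps.
    num_blocks_W: vector-size blocks used in the W-step.
    """

    d0: int = 80
    iterations: int = 100
    algorithm_for_W: str = "lasso"
    ldaW: float = 0.02
    k: int = 4
    ldaU: float = 0.02
    num_blocks_W: int = 1
    seed: int = 0
    prune_empty: bool = True
    nonnegative: bool = True
    early_stop_tol: float | None = None

    def __post_init__(self) -> None:
        if self.d0 < 2:
            raise ValidationError(f"d0 must be >= 2, got {self.d0}")
        if self.iterations < 1:
            raise ValidationError(f"iterations must be >= 1, got {self.iterations}")
        if self.algorithm_for_W not in ("lasso", "omp"):
            raise ValidationError(
                f"algorithm_for_W must be 'lasso' or 'omp', got {self.algorithm_for_W!r}"
            )
        if self.ldaU <= 0 or self.ldaW <= 0:
            raise ValidationError("ldaU and ldaW must be positive")
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.num_blocks_W < 1:
            raise ValidationError(f"num_blocks_W must be >= 1, got {self.num_blocks_W}")


# ---------------------------------------------------------------------------
# array-level core

def _nmf_init_arrays(X: np.ndarray, d0: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    if not X.any():
        raise ValidationError("cannot initialize factorization: X is all zeros")
    p, n = X.shape
    if d0 > min(p, n):
        warnings.warn(
            f"d0={d0} exceeds min(p, n)={min(p, n)}; the factorization is "
            "overcomplete and pruning will determine the effective module count",
            stacklevel=2,
        )
    nmf = NMF(
        n_components=d0,
        init="random",
        random_state=seed,
        max_iter=500,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        U = nmf.fit_transform(X)  # (p, d0)
        W = nmf.components_  # (d0, n)
    return _normalize_modules(U, W)


def _normalize_modules(U: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-L2 module columns of U; W rows rescaled so U @ W is unchanged."""
    norms = np.linalg.norm(U, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    return U / safe, W * safe[:, None]


def _rel_err(X: np.ndarray, U: np.ndarray, W: np.ndarray) -> float:
    return float(((X - U @ W) ** 2).sum() / (X**2).sum())


def _smaf_arrays(
    X: np.ndarray, config: SmafConfig
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run SMAF on a p x n array; returns (U, W, report)."""
    X = np.asarray(X, dtype=float)
    U, W = _nmf_init_arrays(X, config.d0, config.seed)
    history: list[dict] = []
    prev_err = None
    n_infeasible_steps = 0
    for it in range(config.iterations):
        # mid-alternation infeasibility (one factor does not yet span X
        # within tolerance) is routine and resolved by later iterations; it
        # is counted in the report rather than warned per step
        if config.algorithm_for_W == "lasso":
            W, w_info = sparse_decode_lasso(
                X, U, lda=config.ldaW,
                num_blocks=config.num_blocks_W,
                nonnegative=config.nonnegative,
                return_info=True, warn_infeasible=False,
            )
            n_infeasible_steps += not w_info["all_feasible"]
        else:
            W = sparse_decode_omp(X, U, k=config.k, nonnegative=config.nonnegative)
        # U-step on the transposed problem: X^T ~= W^T @ U^T
        Ut, u_info = sparse_decode_lasso(
            X.T, W.T, lda=config.ldaU, num_blocks=1,
            nonnegative=config.nonnegative,
            return_info=True, warn_infeasible=False,
        )
        n_infeasible_steps += not u_info["all_feasible"]
        U = Ut.T
        U, W = _normalize_modules(U, W)
        err = _rel_err(X, U, W)
        history.append(
            {
                "iteration": it,
                "relative_error": err,
                "u_nonzero_fraction": float((U != 0).mean()),
                "w_nonzero_fraction": float((W != 0).mean()),
                "mean_modules_per_cell": float((W != 0).sum(axis=0).mean()),
            }
        )
        if (
            config.early_stop_tol is not None
            and prev_err is not None
            and abs(prev_err - err) <= config.early_stop_tol
        ):
            break
        prev_err = err
    active = (U != 0).any(axis=0) & (W != 0).any(axis=1)
    if config.prune_empty:
        if not active.any():
            raise ValidationError("dictionary collapsed; loosen ldaU")
        U, W = U[:, active], W[active, :]
    report = {
        "history": history,
        "final": dictionary_stats_arrays(U, W, X),
        "n_iterations_run": len(history),
        "n_infeasible_steps": n_infeasible_steps,
        "pruned_modules": int((~active).sum()) if config.prune_empty else 0,
    }
    return U, W, report


def dictionary_stats_arrays(U: np.ndarray, W: np.ndarray, X: np.ndarray) -> dict:
    return {
        "n_modules": int(U.shape[1]),
        "u_nonzero_fraction": float((U != 0).mean()),
        "w_nonzero_fraction": float((W != 0).mean()),
        "mean_modules_per_cell": float((W != 0).sum(axis=0).mean()),
        "relative_error": _rel_err(X, U, W),
    }


# ---------------------------------------------------------------------------
# scikit-learn estimator

class SMAF(TransformerMixin, BaseEstimator):
    """Sparse module activity factorization as a sklearn transformer.

    Follows the ``DictionaryLearning`` conventions: ``fit`` expects
    ``X`` of shape (n_cells, n_proteins), learns ``components_`` of shape
    (n_modules, n_proteins) whose rows are unit-L2 protein-expression
    modules, and ``transform`` returns sparse module activities of shape
    (n_cells, n_modules) obtained with the configured W-step solver.

    Parameters mirror :class:`SmafConfig`; see the module docstring for the
    algorithm.
    """

    def __init__(
        self,
        d0: int = 80,
        iterations: int = 100,
        algorithm_for_W: str = "lasso",
        ldaW: float = 0.02,
        k: int = 4,
        ldaU: float = 0.02,
        num_blocks_W: int = 1,
        nonnegative: bool = True,
        prune_empty: bool = True,
        early_stop_tol: float | None = None,
        random_state: int = 0,
    ) -> None:
        self.d0 = d0
        self.iterations = iterations
        self.algorithm_for_W = algorithm_for_W
        self.ldaW = ldaW
        self.k = k
        self.ldaU = ldaU
        self.num_blocks_W = num_blocks_W
        self.nonnegative = nonnegative
        self.prune_empty = prune_empty
        self.early_stop_tol = early_stop_tol
        self.random_state = random_state

    def _config(self) -> SmafConfig:
        return SmafConfig(
            d0=self.d0,
            iterations=self.iterations,
            algorithm_for_W=self.algorithm_for_W,
            ldaW=self.ldaW,
            k=self.k,
            ldaU=self.ldaU,
            num_blocks_W=self.num_blocks_W,
            seed=self.random_state,
            prune_empty=self.prune_empty,
            nonnegative=self.nonnegative,
            early_stop_tol=self.early_stop_tol,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_cells, n_proteins)")
        U, W, report = _smaf_arrays(X.T, self._config())
        self.components_ = U.T  # (d, p)
        self.activity_ = W.T  # (n, d)
        self.report_ = report
        self.n_features_in_ = X.shape[1]
        self.n_modules_ = U.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        basis = self.components_.T  # (p, d)
        if self.algorithm_for_W == "lasso":
            W = sparse_decode_lasso(
                X.T, basis, lda=self.ldaW,
                num_blocks=self.num_blocks_W, nonnegative=self.nonnegative,
            )
        else:
            W = sparse_decode_omp(X.T, basis, k=self.k, nonnegative=self.nonnegative)
        return W.T

    def inverse_transform(self, W):
        check_is_fitted(self, "components_")
        return np.asarray(W, dtype=float) @ self.components_


# ---------------------------------------------------------------------------
# typed wrappers

def _module_ids(d: int) -> list[str]:
    return [f"m{i}" for i in range(d)]


def nmf_init(
    X: ExpressionMatrix, d0: int = 80, seed: int = 0
) -> tuple[Dictionary, ModuleActivity]:
    """Nonnegative matrix factorization seed for the alternating updates.

    Module columns are rescaled to unit L2 norm (with activities scaled
    inversely) so the returned pair already satisfies the dictionary
    invariant while leaving ``U @ W`` unchanged.
    """
    U, W = _nmf_init_arrays(X.values, d0, seed)
    ids = _module_ids(U.shape[1])
    return (
        Dictionary(U, X.protein_ids, ids),
        ModuleActivity(W, ids, X.cell_ids),
    )


def fit_smaf(
    X: ExpressionMatrix, config: SmafConfig | None = None
) -> tuple[Dictionary, ModuleActivity, dict]:
    """Learn a module dictionary and activities from training expression data.

    Thin wrapper over :class:`SMAF` operating on the typed proteins x cells
    matrices.  Whether to L2-normalize protein rows beforehand (the
    titration blend) is the caller's choice and deliberately not implicit.
    """
    config = config or SmafConfig()
    U, W, report = _smaf_arrays(X.values, config)
    ids = _module_ids(U.shape[1])
    allow_neg = not config.nonnegative
    return (
        Dictionary(U, X.protein_ids, ids, allow_negative=allow_neg),
        ModuleActivity(W, ids, X.cell_ids, allow_negative=allow_neg),
        report,
    )


def dictionary_stats(U: Dictionary, W: ModuleActivity, X: ExpressionMatrix) -> dict:
    """Sparsity and reconstruction summary for a fitted (U, W) pair."""
    if U.values.shape[1] != W.values.shape[0]:
        raise ValidationError(
            f"dictionary has {U.values.shape[1]} modules but activity has "
            f"{W.values.shape[0]}"
        )
    if U.values.shape[0] != X.values.shape[0] or W.values.shape[1] != X.values.shape[1]:
        raise ValidationError("dictionary/activity shapes do not match X")
    return dictionary_stats_arrays(U.values, W.values, X.values)
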