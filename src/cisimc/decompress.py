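"""Decompression: recover per-protein expression from composite channels.

Given measured (or simulated) composite intensities ``Y = A @ X`` with a
known barcoding matrix ``A`` and a pre-trained module dictionary ``U``, the
sparsest module activity ``W`` satisfying

    min ||W||_1   s.t.   ||Y - A U W||_F^2 <= lda * ||Y||_F^2

is estimated with the error-constrained Lasso, and expression is
reconstructed as ``X_hat = U @ W``.  Cells decode independently, so results
do not depend on batching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import (
    BarcodingMatrix,
    CompositeMatrix,
    Dictionary,
    ExpressionMatrix,
    ModuleActivity,
    ValidationError,
)
from .sparse_coding import sparse_decode_lasso

__all__ = [
    "DecompressConfig",
    "Decompressor",
    "estimate_activity",
    "reconstruct",
    "decompress",
]


@dataclass
class DecompressConfig:
    """Decoding tolerance and blocking for the activity estimate.

    ``lda`` defaults to 0.02, matching the W-step tolerance used during
    dictionary training.
    """

    lda: float = 0.02
    num_blocks: int = 1
    nonnegative: bool = True

    def __post_init__(self) -> None:
        if not self.lda > 0:
            raise ValidationError(f"lda must be positive, got {self.lda}")
        if self.num_blocks < 1:
            raise ValidationError(f"num_blocks must be >= 1, got {self.num_blocks}")


def _check_ids_equal(left, right, what: str) -> None:
    if list(left) != list(right):
        missing = sorted(set(left) ^ set(right))
        detail = f"; unmatched ids: {', '.join(missing[:8])}" if missing else " (order differs)"
        raise ValidationError(f"{what} do not match{detail}")


class Decompressor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from composite to per-protein expression.

    Parameters
    ----------
    barcoding_matrix : array-like (m, p) or BarcodingMatrix
    dictionary : array-like (p, d) or Dictionary
    lda : relative squared-error tolerance of the activity decode
    num_blocks : vector-size cell blocks for the decode
    nonnegative : constrain activities (and hence expression) to be >= 0

    ``transform`` maps ``Y`` of shape (n_cells, m) to ``X_hat`` of shape
    (n_cells, p); ``fit`` only validates the design.
    """

    def __init__(
        self,
        barcoding_matrix=None,
        dictionary=None,
        lda: float = 0.02,
        num_blocks: int = 1,
        nonnegative: bool = True,
    ) -> None:
        self.barcoding_matrix = barcoding_matrix
        self.dictionary = dictionary
        self.lda = lda
        self.num_blocks = num_blocks
        self.nonnegative = nonnegative

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self.barcoding_matrix is None or self.dictionary is None:
            raise ValidationError("barcoding_matrix and dictionary are required")
        A = np.asarray(getattr(self.barcoding_matrix, "values", self.barcoding_matrix), dtype=float)
        U = np.asarray(getattr(self.dictionary, "values", self.dictionary), dtype=float)
        if A.ndim != 2 or U.ndim != 2:
            raise ValidationError("barcoding matrix and dictionary must be 2-D")
        if A.shape[1] != U.shape[0]:
            raise ValidationError(
                f"barcoding matrix covers {A.shape[1]} proteins but dictionary has "
                f"{U.shape[0]}"
            )
        return A, U

    def fit(self, X=None, y=None):
        A, U = self._arrays()
        DecompressConfig(lda=self.lda, num_blocks=self.num_blocks)
        self.design_ = A @ U  # (m, d) composite signature of each module
        self.n_channels_ = A.shape[0]
        self.n_proteins_ = A.shape[1]
        self.n_modules_ = U.shape[1]
        return self

    def transform(self, Y):
        check_is_fitted(self, "design_")
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != self.n_channels_:
            raise ValidationError(
                f"Y must have shape (n_cells, {self.n_channels_}), got {Y.shape}"
            )
        W = sparse_decode_lasso(
            Y.T, self.design_, lda=self.lda,
            num_blocks=self.num_blocks, nonnegative=self.nonnegative,
        )
        _, U = self._arrays()
        return (U @ W).T

    def transform_activity(self, Y):
        """Module activities (n_cells, d) instead of reconstructed expression."""
        check_is_fitted(self, "design_")
        Y = np.asarray(Y, dtype=float)
        W = sparse_decode_lasso(
            Y.T, self.design_, lda=self.lda,
            num_blocks=self.num_blocks, nonnegative=self.nonnegative,
        )
        return W.T


# ---------------------------------------------------------------------------
# typed wrappers

def estimate_activity(
    Y: CompositeMatrix,
    A: BarcodingMatrix,
    U: Dictionary,
    config: DecompressConfig | None = None,
) -> ModuleActivity:
    """Sparsest W with ||Y - A U W||^2 within ``lda`` of ||Y||^2."""
    config = config or DecompressConfig()
    _check_ids_equal(Y.channel_ids, A.channel_ids, "channel ids of Y and A")
    _check_ids_equal(A.protein_ids, U.protein_ids, "protein ids of A and U")
    basis = A.values @ U.values
    W = sparse_decode_lasso(
        Y.values, basis, lda=config.lda,
        num_blocks=config.num_blocks, nonnegative=config.nonnegative,
    )
    return ModuleActivity(
        W, U.module_ids, Y.cell_ids, allow_negative=not config.nonnegative
    )


def reconstruct(U: Dictionary, W: ModuleActivity) -> ExpressionMatrix:
    """Decompressed expression X_hat = U @ W."""
    _check_ids_equal(U.module_ids, W.module_ids, "module ids of U and W")
    values = U.values @ W.values
    if values.min() < 0:
        # only reachable with sign-unconstrained factors
        values = np.maximum(values, 0.0)
    return ExpressionMatrix(values, U.protein_ids, W.cell_ids)


def decompress(
    Y: CompositeMatrix,
    A: BarcodingMatrix,
    U: Dictionary,
    config: DecompressConfig | None = None,
) -> ExpressionMatrix:
    """Full decode: estimate activities from Y, then reconstruct U @ W."""
    config = config or DecompressConfig()
    return reconstruct(U, estimate_activity(Y, A, U, config))
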