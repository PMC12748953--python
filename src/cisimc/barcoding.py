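"""Barcoding-matrix generation, composite simulation, and random search.

A barcoding matrix ``A`` (channels x proteins) states which isotope channels
label each antibody.  Practical labeling constraints shape the random
designs: at most two channels per protein, at most four proteins on a single
channel (denser designs decode better), no empty channel, and pairwise
distinct barcodes.  Candidate matrices are scored by simulating the full
decompression loop — ``Y = A X``, sparse decode of ``W``, ``X_hat = U W`` —
on held-out cells and ranked by the Pearson correlation of the *worst*
protein, so a design cannot win by sacrificing one marker.

The search mirrors a two-round tournament: several independent passes each
score a fresh pool of random candidates on a fresh evaluation subsample and
keep the best few; a second set of passes rescores the pooled finalists, and
the winner maximizes the across-pass mean of the minimum protein
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import (
    BarcodingMatrix,
    CompositeMatrix,
    Dictionary,
    ExpressionMatrix,
    ValidationError,
)
from .decompress import DecompressConfig, decompress
from .evaluate import EvaluationReport, correlation_report

__all__ = [
    "BarcodeSearchConfig",
    "random_barcoding_matrix",
    "simulate_composite",
    "score_barcoding_matrix",
    "search_barcoding",
    "BarcodingMatrixSearch",
]


@dataclass
class BarcodeSearchConfig:
    """Constraints and schedule of the random design search.

    Defaults reproduce the full-scale protocol: 4 passes x 2000 fresh
    candidates, top 50 per pass (200 finalists), scored on 25% cell
    subsamples with decode tolerance 0.02.
    """

    m: int = 8
    p: int = 16
    max_channels_per_protein: int = 2
    max_single_channel_proteins: int = 4
    n_candidates_per_round: int = 2000
    n_rounds: int = 4
    top_per_round: int = 50
    lda_decode: float = 0.02
    eval_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.p < 1:
            raise ValidationError("m and p must be >= 1")
        if self.m >= self.p:
            raise ValidationError(
                f"compression requires m < p, got m={self.m}, p={self.p}"
            )
        if self.max_channels_per_protein < 1:
            raise ValidationError("max_channels_per_protein must be >= 1")
        if self.max_single_channel_proteins < 0:
            raise ValidationError("max_single_channel_proteins must be >= 0")
        if self.top_per_round > self.n_candidates_per_round:
            raise ValidationError(
                "top_per_round cannot exceed n_candidates_per_round"
            )
        if not self.lda_decode > 0:
            raise ValidationError("lda_decode must be positive")
        if not (0 < self.eval_fraction <= 1):
            raise ValidationError("eval_fraction must lie in (0, 1]")


def _feasibility_check(config: BarcodeSearchConfig) -> None:
    m, maxc = config.m, config.max_channels_per_protein
    n_codes = sum(comb(m, c) for c in range(1, min(maxc, m) + 1))
    if config.p > n_codes:
        raise ValidationError(
            f"only {n_codes} distinct barcodes exist for m={m} channels with at "
            f"most {maxc} channels per protein; cannot barcode {config.p} proteins"
        )
    n_multi = sum(comb(m, c) for c in range(2, min(maxc, m) + 1))
    if config.p - config.max_single_channel_proteins > n_multi:
        raise ValidationError(
            f"at most {config.max_single_channel_proteins} single-channel "
            f"proteins allowed but only {n_multi} multi-channel barcodes exist "
            f"for {config.p} proteins"
        )


def random_barcoding_matrix(
    config: BarcodeSearchConfig,
    rng: np.random.Generator | None = None,
    protein_ids=None,
    channel_ids=None,
    max_attempts: int = 1000,
) -> BarcodingMatrix:
    """Draw one constrained random design.

    Each protein draws a channel count in {1, ..., max_channels_per_protein}
    (excess single-channel proteins are promoted to two channels) and then
    that many distinct channels uniformly; draws with duplicate barcodes or
    an empty channel are rejected and resampled whole.
    """
    _feasibility_check(config)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m, p = config.m, config.p
    maxc = min(config.max_channels_per_protein, m)
    if protein_ids is None:
        protein_ids = [f"p{i}" for i in range(p)]
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(m)]
    for _ in range(max_attempts):
        counts = rng.integers(1, maxc + 1, size=p)
        singles = np.nonzero(counts == 1)[0]
        excess = singles.size - config.max_single_channel_proteins
        if excess > 0:
            promote = rng.choice(singles, size=excess, replace=False)
            counts[promote] = 2 if maxc >= 2 else 1
        A = np.zeros((m, p))
        for j, c in enumerate(counts):
            A[rng.choice(m, size=int(c), replace=False), j] = 1.0
        codes = {tuple(A[:, j].astype(int)) for j in range(p)}
        if len(codes) < p or (A.sum(axis=1) == 0).any():
            continue
        return BarcodingMatrix(
            A,
            channel_ids,
            protein_ids,
            max_channels_per_protein=config.max_channels_per_protein,
            max_single_channel_proteins=config.max_single_channel_proteins,
        )
    raise ValidationError(
        f"failed to sample a valid barcoding matrix in {max_attempts} attempts; "
        "constraints may be near-unsatisfiable"
    )


def simulate_composite(A: BarcodingMatrix, X: ExpressionMatrix) -> CompositeMatrix:
    """Composite intensities Y = A @ X from uncompressed expression."""
    if list(A.protein_ids) != list(X.protein_ids):
        missing = sorted(set(A.protein_ids) ^ set(X.protein_ids))
        detail = ", ".join(missing[:8]) if missing else "(order differs)"
        raise ValidationError(f"protein ids of A and X do not match: {detail}")
    return CompositeMatrix(A.values @ X.values, A.channel_ids, X.cell_ids)


def score_barcoding_matrix(
    A: BarcodingMatrix,
    U: Dictionary,
    X: ExpressionMatrix,
    lda_decode: float = 0.02,
) -> EvaluationReport:
    """Simulated decompression accuracy of one design on evaluation cells."""
    Y = simulate_composite(A, X)
    X_hat = decompress(Y, A, U, DecompressConfig(lda=lda_decode))
    return correlation_report(X, X_hat)


def _score_many(
    candidates: list[BarcodingMatrix],
    U: Dictionary,
    X_eval: ExpressionMatrix,
    lda: float,
) -> tuple[np.ndarray, np.ndarray]:
    import warnings as _warnings

    from .sparse_coding import InfeasibleDecodeWarning

    min_r = np.empty(len(candidates))
    mean_r = np.empty(len(candidates))
    # a candidate whose decode is infeasible simply scores poorly; no need
    # to warn once per candidate during a large search
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", InfeasibleDecodeWarning)
        for i, A in enumerate(candidates):
            report = score_barcoding_matrix(A, U, X_eval, lda)
            min_r[i] = report.min_protein_r
            mean_r[i] = report.mean_protein_r
    return min_r, mean_r


def _eval_subset(
    X: ExpressionMatrix, fraction: float, rng: np.random.Generator
) -> ExpressionMatrix:
    n = X.n_cells
    n_eval = max(1, int(round(n * fraction)))
    cols = np.sort(rng.choice(n, size=n_eval, replace=False))
    return ExpressionMatrix(
        X.values[:, cols], X.protein_ids, [X.cell_ids[i] for i in cols]
    )


def search_barcoding(
    X_train: ExpressionMatrix,
    U: Dictionary,
    config: BarcodeSearchConfig,
) -> tuple[BarcodingMatrix, pd.DataFrame]:
    """Two-round random search for the best-decoding barcoding matrix.

    Round 1 runs ``n_rounds`` independent passes; each scores
    ``n_candidates_per_round`` fresh random designs on a fresh
    ``eval_fraction`` cell subsample and keeps the ``top_per_round`` by
    minimum protein correlation.  Round 2 rescores the pooled finalists over
    ``n_rounds`` fresh subsamples; the winner maximizes the across-pass mean
    of the minimum protein correlation (ties: higher mean protein
    correlation, then lower candidate index).

    Returns the winning matrix and a ranking table over all finalists.
    """
    if list(X_train.protein_ids) != list(U.protein_ids):
        raise ValidationError("protein ids of X_train and U do not match")
    rng = np.random.default_rng(config.seed)
    finalists: list[BarcodingMatrix] = []
    origin: list[tuple[int, int]] = []  # (round-1 pass, rank within pass)
    for pass_idx in range(config.n_rounds):
        X_eval = _eval_subset(X_train, config.eval_fraction, rng)
        candidates = [
            random_barcoding_matrix(config, rng, protein_ids=list(X_train.protein_ids))
            for _ in range(config.n_candidates_per_round)
        ]
        min_r, _ = _score_many(candidates, U, X_eval, config.lda_decode)
        top = np.argsort(-min_r, kind="stable")[: config.top_per_round]
        for rank, idx in enumerate(top):
            finalists.append(candidates[idx])
            origin.append((pass_idx, rank))
    n_final = len(finalists)
    min_scores = np.empty((config.n_rounds, n_final))
    mean_scores = np.empty((config.n_rounds, n_final))
    for pass_idx in range(config.n_rounds):
        X_eval = _eval_subset(X_train, config.eval_fraction, rng)
        min_scores[pass_idx], mean_scores[pass_idx] = _score_many(
            finalists, U, X_eval, config.lda_decode
        )
    avg_min = min_scores.mean(axis=0)
    avg_mean = mean_scores.mean(axis=0)
    order = np.lexsort((np.arange(n_final), -avg_mean, -avg_min))
    ranking = pd.DataFrame(
        {
            "candidate": order,
            "round1_pass": [origin[i][0] for i in order],
            "round1_rank": [origin[i][1] for i in order],
            "mean_min_protein_r": avg_min[order],
            "mean_mean_protein_r": avg_mean[order],
        }
    ).reset_index(drop=True)
    best = finalists[order[0]]
    return best, ranking


class BarcodingMatrixSearch(BaseEstimator):
    """Sklearn-style wrapper around the two-round design search.

    ``fit(X)`` expects expression of shape (n_cells, n_proteins) and a
    ``dictionary`` of shape (n_proteins, n_modules); afterwards
    ``best_matrix_`` holds the winning (m, p) binary design and ``ranking_``
    the finalist table.
    """

    def __init__(
        self,
        m: int = 8,
        dictionary=None,
        max_channels_per_protein: int = 2,
        max_single_channel_proteins: int = 4,
        n_candidates_per_round: int = 2000,
        n_rounds: int = 4,
        top_per_round: int = 50,
        lda_decode: float = 0.02,
        eval_fraction: float = 0.25,
        random_state: int = 0,
    ) -> None:
        self.m = m
        self.dictionary = dictionary
        self.max_channels_per_protein = max_channels_per_protein
        self.max_single_channel_proteins = max_single_channel_proteins
        self.n_candidates_per_round = n_candidates_per_round
        self.n_rounds = n_rounds
        self.top_per_round = top_per_round
        self.lda_decode = lda_decode
        self.eval_fraction = eval_fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_cells, n_proteins)")
        if self.dictionary is None:
            raise ValidationError("a fitted dictionary is required")
        Uarr = np.asarray(getattr(self.dictionary, "values", self.dictionary), dtype=float)
        p = X.shape[1]
        protein_ids = [f"p{i}" for i in range(p)]
        X_dom = ExpressionMatrix(
            X.T, protein_ids, [f"c{i}" for i in range(X.shape[0])]
        )
        U_dom = Dictionary(
            Uarr, protein_ids, [f"m{i}" for i in range(Uarr.shape[1])],
            allow_negative=bool((Uarr < 0).any()),
        )
        config = BarcodeSearchConfig(
            m=self.m,
            p=p,
            max_channels_per_protein=self.max_channels_per_protein,
            max_single_channel_proteins=self.max_single_channel_proteins,
            n_candidates_per_round=self.n_candidates_per_round,
            n_rounds=self.n_rounds,
            top_per_round=self.top_per_round,
            lda_decode=self.lda_decode,
            eval_fraction=self.eval_fraction,
            seed=self.random_state,
        )
        best, ranking = search_barcoding(X_dom, U_dom, config)
        self.best_matrix_ = best.values
        self.best_design_ = best
        self.ranking_ = ranking
        self.n_features_in_ = p
        return self
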