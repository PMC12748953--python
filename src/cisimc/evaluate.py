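"""Decompression performance metrics and dictionary-selection harnesses.

Accuracy is summarized with Pearson correlations computed separately per
protein (across cells) and per cell (across proteins): the mean and minimum
protein correlations and the mean cell correlation.  Correlations are
computed on intensities as given (no variance-stabilizing transform).
Zero-variance series are reported as r = 0 with an explicit flag so the
summaries stay defined while degeneracies remain auditable.

The module also hosts the dictionary-selection harnesses: a parameter sweep
scoring each hyperparameter condition with many random barcoding matrices on
a held-out cell split, and a leave-one-tissue-out stability check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CompositeMatrix,
    ExpressionMatrix,
    ValidationError,
)
from .smaf import SmafConfig, fit_smaf

__all__ = [
    "EvaluationReport",
    "correlation_report",
    "channel_agreement",
    "sweep_dictionary_params",
    "leave_one_group_out",
    "export_aligned_tables",
]


@dataclass
class EvaluationReport:
    """Per-protein and per-cell Pearson summaries of a decompression run."""

    per_protein_r: dict
    mean_protein_r: float
    min_protein_r: float
    mean_cell_r: float
    per_channel_r: dict | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "per_protein_r": dict(self.per_protein_r),
            "mean_protein_r": self.mean_protein_r,
            "min_protein_r": self.min_protein_r,
            "mean_cell_r": self.mean_cell_r,
            "flags": list(self.flags),
        }
        if self.per_channel_r is not None:
            out["per_channel_r"] = dict(self.per_channel_r)
        return out


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r between paired rows; zero-variance rows flagged."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    degenerate = (na == 0) | (nb == 0)
    denom = np.where(degenerate, 1.0, na * nb)
    r = (ac * bc).sum(axis=1) / denom
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate


def _align(X_truth: ExpressionMatrix, X_hat: ExpressionMatrix) -> np.ndarray:
    """Return X_hat.values reordered to X_truth's protein and cell ids."""
    if set(X_truth.protein_ids) != set(X_hat.protein_ids):
        missing = sorted(set(X_truth.protein_ids) ^ set(X_hat.protein_ids))
        raise ValidationError(f"protein ids do not match; unmatched: {missing[:8]}")
    if set(X_truth.cell_ids) != set(X_hat.cell_ids):
        raise ValidationError("cell ids do not match")
    if (
        list(X_truth.protein_ids) == list(X_hat.protein_ids)
        and list(X_truth.cell_ids) == list(X_hat.cell_ids)
    ):
        return X_hat.values
    frame = X_hat.to_frame().reindex(
        index=X_truth.protein_ids, columns=X_truth.cell_ids
    )
    return frame.to_numpy(dtype=float)


def correlation_report(
    X_truth: ExpressionMatrix, X_hat: ExpressionMatrix
) -> EvaluationReport:
    """Pearson correlations between truth and decompressed expression.

    Per-protein r is computed across cells and summarized by mean and
    minimum; per-cell r is computed across proteins and averaged.
    Zero-variance proteins or cells contribute r = 0 and a flag.
    """
    hat = _align(X_truth, X_hat)
    prot_r, prot_deg = _pearson_rows(X_truth.values, hat)
    cell_r, cell_deg = _pearson_rows(X_truth.values.T, hat.T)
    flags = [
        f"protein {X_truth.protein_ids[i]}: zero variance; r set to 0"
        for i in np.nonzero(prot_deg)[0]
    ]
    n_deg_cells = int(cell_deg.sum())
    if n_deg_cells:
        flags.append(f"{n_deg_cells} cell(s) with zero variance; r set to 0")
    return EvaluationReport(
        per_protein_r={pid: float(r) for pid, r in zip(X_truth.protein_ids, prot_r)},
        mean_protein_r=float(prot_r.mean()),
        min_protein_r=float(prot_r.min()),
        mean_cell_r=float(cell_r.mean()),
        flags=flags,
    )


def channel_agreement(
    Y_measured: CompositeMatrix, Y_simulated: CompositeMatrix
) -> dict:
    """Per-channel Pearson r between measured and simulated composite data.

    Used to check that ``Y = A @ X`` faithfully models the physical channel
    summation.  Degenerate (constant) channels yield r = 0 with a warning.
    """
    if list(Y_measured.channel_ids) != list(Y_simulated.channel_ids):
        raise ValidationError("channel ids do not match")
    if list(Y_measured.cell_ids) != list(Y_simulated.cell_ids):
        raise ValidationError("cell ids do not match")
    r, degenerate = _pearson_rows(Y_measured.values, Y_simulated.values)
    if degenerate.any():
        import warnings

        names = [Y_measured.channel_ids[i] for i in np.nonzero(degenerate)[0]]
        warnings.warn(
            f"zero-variance channel(s) {', '.join(names)}: r set to 0",
            stacklevel=2,
        )
    return {cid: float(v) for cid, v in zip(Y_measured.channel_ids, r)}


# ---------------------------------------------------------------------------
# dictionary-selection harnesses


def _split_cells(
    n: int, eval_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_eval = max(1, int(round(n * eval_fraction)))
    perm = rng.permutation(n)
    return np.sort(perm[n_eval:]), np.sort(perm[:n_eval])


def _subset(X: ExpressionMatrix, cols: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(
        X.values[:, cols], X.protein_ids, [X.cell_ids[i] for i in cols]
    )


def sweep_dictionary_params(
    X: ExpressionMatrix,
    grid: Sequence[SmafConfig | Mapping],
    n_random_A: int = 200,
    split_fraction: float = 0.25,
    m: int = 8,
    lda_decode: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Score SMAF hyperparameter conditions by simulated decompression.

    For each condition a dictionary is fitted on ``1 - split_fraction`` of
    the cells and ``n_random_A`` random barcoding matrices with ``m``
    channels are scored on the held-out fraction.  Returns one row per
    (condition, matrix) with the mean/min protein and mean cell
    correlations, ready for distribution plots or ranking.
    """
    from .barcoding import BarcodeSearchConfig, random_barcoding_matrix, score_barcoding_matrix

    if not grid:
        raise ValidationError("parameter grid must be nonempty")
    if not (0 < split_fraction < 1):
        raise ValidationError("split_fraction must lie in (0, 1)")
    rows = []
    root = np.random.default_rng(seed)
    for cond_idx, cond in enumerate(grid):
        config = cond if isinstance(cond, SmafConfig) else SmafConfig(**dict(cond))
        rng = np.random.default_rng(root.integers(2**31))
        train_cols, eval_cols = _split_cells(X.n_cells, split_fraction, rng)
        U, _, _ = fit_smaf(_subset(X, train_cols), config)
        X_eval = _subset(X, eval_cols)
        bc = BarcodeSearchConfig(
            m=m, p=X.n_proteins, lda_decode=lda_decode, seed=int(rng.integers(2**31))
        )
        for a_idx in range(n_random_A):
            A = random_barcoding_matrix(bc, rng, protein_ids=X.protein_ids)
            report = score_barcoding_matrix(A, U, X_eval, lda_decode)
            rows.append(
                {
                    "condition": cond_idx,
                    "algorithm_for_W": config.algorithm_for_W,
                    "ldaU": config.ldaU,
                    "ldaW": config.ldaW,
                    "k": config.k,
                    "num_blocks_W": config.num_blocks_W,
                    "matrix": a_idx,
                    "mean_protein_r": report.mean_protein_r,
                    "min_protein_r": report.min_protein_r,
                    "mean_cell_r": report.mean_cell_r,
                }
            )
    return pd.DataFrame(rows)


def leave_one_group_out(
    X: ExpressionMatrix,
    groups: Sequence[str],
    smaf_config: SmafConfig | None = None,
    n_random_A: int = 200,
    m: int = 8,
    lda_decode: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability across tissues: fit on all-but-one group, score on it.

    ``groups`` assigns a tissue label to every cell.  For each group a
    dictionary is trained on the remaining cells and ``n_random_A`` random
    barcoding matrices are scored on the held-out group; scores averaged
    across groups estimate how well the module vocabulary transfers to an
    unseen tissue.
    """
    from .barcoding import BarcodeSearchConfig, random_barcoding_matrix, score_barcoding_matrix

    groups = [str(g) for g in groups]
    if len(groups) != X.n_cells:
        raise ValidationError(
            f"expected {X.n_cells} group labels, got {len(groups)}"
        )
    unique = sorted(set(groups))
    if len(unique) < 2:
        raise ValidationError("need at least 2 groups")
    labels = np.asarray(groups)
    smaf_config = smaf_config or SmafConfig()
    root = np.random.default_rng(seed)
    rows = []
    for g in unique:
        held = np.nonzero(labels == g)[0]
        rest = np.nonzero(labels != g)[0]
        if rest.size == 0:
            raise ValidationError(f"group {g} contains all cells")
        rng = np.random.default_rng(root.integers(2**31))
        U, _, _ = fit_smaf(_subset(X, rest), smaf_config)
        X_eval = _subset(X, held)
        bc = BarcodeSearchConfig(
            m=m, p=X.n_proteins, lda_decode=lda_decode, seed=int(rng.integers(2**31))
        )
        for a_idx in range(n_random_A):
            A = random_barcoding_matrix(bc, rng, protein_ids=X.protein_ids)
            report = score_barcoding_matrix(A, U, X_eval, lda_decode)
            rows.append(
                {
                    "group": g,
                    "matrix": a_idx,
                    "mean_protein_r": report.mean_protein_r,
                    "min_protein_r": report.min_protein_r,
                    "mean_cell_r": report.mean_cell_r,
                    "n_flags": len(report.flags),
                }
            )
    return pd.DataFrame(rows)


def export_aligned_tables(
    X_truth: ExpressionMatrix, X_hat: ExpressionMatrix, truth_path, hat_path
) -> None:
    """Write id-aligned truth/decompressed tables for external classifiers."""
    from .core import save_matrix

    hat = ExpressionMatrix(_align(X_truth, X_hat), X_truth.protein_ids, X_truth.cell_ids)
    save_matrix(X_truth, truth_path)
    save_matrix(hat, hat_path)
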