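"""Typed single-cell matrices, delimited-table I/O, and titration normalization.

The data model mirrors the compressed-sensing view of multiplexed antibody
imaging.  Single-cell protein expression ``X`` (proteins x cells) is
approximated as ``U @ W``: a dictionary ``U`` of protein-expression modules
(each a unit-L2 column) times sparse per-cell module activities ``W``.
A binary barcoding matrix ``A`` (channels x proteins) states which isotope
channels label each antibody, so that a measurement collapses ``X`` into
composite intensities ``Y = A @ X`` with fewer channels than proteins.

All matrices are stored proteins/modules/channels as rows and cells/proteins
as columns, matching the formulas above; on disk they are plain CSV tables
with one header row, one label column and an optional ``# role=...`` comment.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "ExpressionMatrix",
    "Dictionary",
    "ModuleActivity",
    "BarcodingMatrix",
    "CompositeMatrix",
    "NormalizationSpec",
    "load_matrix",
    "save_matrix",
    "l2_normalize_proteins",
    "weighted_normalize",
]


class ValidationError(ValueError):
    """A matrix violates one of its structural invariants."""


class FormatError(ValueError):
    """A delimited table could not be parsed."""


# ---------------------------------------------------------------------------
# validation helpers

def _finite_2d(values, what: str, *, nonnegative: bool = False) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{what}: expected a 2-D matrix, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError(f"{what}: matrix must be at least 1x1, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{what}: NaN or Inf entries are not allowed")
    if nonnegative and (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{what}: negative entry {arr[i, j]!r} at row {i}, column {j}"
        )
    return arr


def _check_ids(ids: Sequence, expected: int, what: str) -> list[str]:
    out = [str(i) for i in ids]
    if len(out) != expected:
        raise ValidationError(
            f"{what}: expected {expected} identifiers, got {len(out)}"
        )
    if any(i == "" for i in out):
        raise ValidationError(f"{what}: empty identifiers are not allowed")
    if len(set(out)) != len(out):
        raise ValidationError(f"{what}: identifiers must be unique")
    return out


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ExpressionMatrix:
    """Nonnegative proteins x cells intensities (mean ion counts per cell)."""

    values: np.ndarray
    protein_ids: Sequence[str]
    cell_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = _finite_2d(self.values, "expression values", nonnegative=True)
        self.protein_ids = _check_ids(self.protein_ids, self.values.shape[0], "protein_ids")
        self.cell_ids = _check_ids(self.cell_ids, self.values.shape[1], "cell_ids")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.cell_ids)


@dataclass
class Dictionary:
    """Proteins x modules matrix; every nonzero module column has unit L2 norm.

    Nonnegativity is the default because the factorization is seeded by NMF
    and ion counts are nonnegative; pass ``allow_negative=True`` for variants
    fitted without the sign constraint.
    """

    values: np.ndarray
    protein_ids: Sequence[str]
    module_ids: Sequence[str]
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.values = _finite_2d(self.values, "dictionary values")
        if not self.allow_negative and (self.values < 0).any():
            raise ValidationError("dictionary values must be nonnegative")
        norms = np.linalg.norm(self.values, axis=0)
        bad = np.nonzero((norms > 0) & (np.abs(norms - 1.0) > 1e-8))[0]
        if bad.size:
            raise ValidationError(
                f"dictionary module at column {bad[0]} has L2 norm "
                f"{norms[bad[0]]:.6g}; nonzero modules must be unit-norm"
            )
        self.protein_ids = _check_ids(self.protein_ids, self.values.shape[0], "protein_ids")
        self.module_ids = _check_ids(self.module_ids, self.values.shape[1], "module_ids")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_modules(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.module_ids)


@dataclass
class ModuleActivity:
    """Sparse modules x cells coefficients pairing a Dictionary with cells."""

    values: np.ndarray
    module_ids: Sequence[str]
    cell_ids: Sequence[str]
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.values = _finite_2d(self.values, "module activity values")
        if not self.allow_negative and (self.values < 0).any():
            raise ValidationError("module activity values must be nonnegative")
        self.module_ids = _check_ids(self.module_ids, self.values.shape[0], "module_ids")
        self.cell_ids = _check_ids(self.cell_ids, self.values.shape[1], "cell_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.module_ids, columns=self.cell_ids)


@dataclass
class BarcodingMatrix:
    """Binary channels x proteins labeling design.

    Constraints reflect practical antibody labeling: each protein may carry at
    most ``max_channels_per_protein`` isotopes (default 2), at most
    ``max_single_channel_proteins`` proteins may use a single isotope
    (default 4, enforcing a dense design), no channel may be empty, and —
    unless ``require_unique_barcodes`` is disabled — no two proteins may share
    a barcode, since identical columns are indistinguishable at the channel
    level.
    """

    values: np.ndarray
    channel_ids: Sequence[str]
    protein_ids: Sequence[str]
    max_channels_per_protein: int = 2
    max_single_channel_proteins: int = 4
    require_unique_barcodes: bool = True

    def __post_init__(self) -> None:
        arr = _finite_2d(self.values, "barcoding values")
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValidationError("barcoding values must be binary {0, 1}")
        self.values = arr
        self.channel_ids = _check_ids(self.channel_ids, arr.shape[0], "channel_ids")
        self.protein_ids = _check_ids(self.protein_ids, arr.shape[1], "protein_ids")
        col_sums = arr.sum(axis=0).astype(int)
        for j, s in enumerate(col_sums):
            if s == 0:
                raise ValidationError(
                    f"column {self.protein_ids[j]} has no channel; every protein "
                    "must be labeled"
                )
            if s > self.max_channels_per_protein:
                raise ValidationError(
                    f"column {self.protein_ids[j]} has {s} channels, max is "
                    f"{self.max_channels_per_protein}"
                )
        n_single = int((col_sums == 1).sum())
        if n_single > self.max_single_channel_proteins:
            raise ValidationError(
                f"{n_single} proteins use a single channel, max is "
                f"{self.max_single_channel_proteins}"
            )
        row_sums = arr.sum(axis=1)
        empty = np.nonzero(row_sums == 0)[0]
        if empty.size:
            raise ValidationError(
                f"channel {self.channel_ids[empty[0]]} labels no protein"
            )
        if self.require_unique_barcodes:
            codes = [tuple(arr[:, j].astype(int)) for j in range(arr.shape[1])]
            if len(set(codes)) != len(codes):
                seen: dict[tuple, int] = {}
                for j, c in enumerate(codes):
                    if c in seen:
                        raise ValidationError(
                            f"columns {self.protein_ids[seen[c]]} and "
                            f"{self.protein_ids[j]} share the same barcode"
                        )
                    seen[c] = j

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channel_ids, columns=self.protein_ids)


@dataclass
class CompositeMatrix:
    """Nonnegative channels x cells composite intensities (measured or simulated)."""

    values: np.ndarray
    channel_ids: Sequence[str]
    cell_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = _finite_2d(self.values, "composite values", nonnegative=True)
        self.channel_ids = _check_ids(self.channel_ids, self.values.shape[0], "channel_ids")
        self.cell_ids = _check_ids(self.cell_ids, self.values.shape[1], "cell_ids")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channel_ids, columns=self.cell_ids)


@dataclass
class NormalizationSpec:
    """Weight ``wt`` of the titration-emulating blend wt*X1 + (1-wt)*X."""

    wt: float

    def __post_init__(self) -> None:
        wt = float(self.wt)
        if not np.isfinite(wt) or not (0.0 <= wt <= 1.0):
            raise ValidationError(f"normalization weight must lie in [0, 1], got {self.wt}")
        self.wt = wt


# ---------------------------------------------------------------------------
# delimited-table I/O

_ROLE_BUILDERS = {
    "expression": lambda v, r, c: ExpressionMatrix(v, r, c),
    "dictionary": lambda v, r, c: Dictionary(v, r, c),
    "activity": lambda v, r, c: ModuleActivity(v, r, c),
    "barcoding": lambda v, r, c: BarcodingMatrix(v, r, c),
    "composite": lambda v, r, c: CompositeMatrix(v, r, c),
}

_ROLE_OF_TYPE = {
    ExpressionMatrix: "expression",
    Dictionary: "dictionary",
    ModuleActivity: "activity",
    BarcodingMatrix: "barcoding",
    CompositeMatrix: "composite",
}


def save_matrix(matrix, path) -> None:
    """Write a typed matrix as CSV with a leading ``# role=<role>`` comment.

    Values are written with 17 significant digits so load/save round trips
    are lossless to double precision.
    """
    role = _ROLE_OF_TYPE.get(type(matrix))
    if role is None:
        raise ValidationError(f"unsupported matrix type {type(matrix).__name__}")
    df = matrix.to_frame()
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# role={role}\n")
            df.to_csv(fh, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"could not write matrix to {path}: {exc}") from exc


def load_matrix(path, role: str):
    """Read a delimited table and validate it as the matrix type for ``role``.

    ``role`` is one of expression/dictionary/activity/barcoding/composite.
    A ``# role=...`` comment in the file, if present, must agree.
    """
    if role not in _ROLE_BUILDERS:
        raise ValidationError(
            f"unknown role {role!r}; expected one of {sorted(_ROLE_BUILDERS)}"
        )
    try:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc

    body: list[str] = []
    body_linenos: list[int] = []
    file_role = None
    for lineno, line in enumerate(lines, start=1):
        if line.lstrip().startswith("#"):
            stripped = line.lstrip("# \t").strip()
            if stripped.startswith("role="):
                file_role = stripped.split("=", 1)[1].strip()
            continue
        if line.strip():
            body.append(line)
            body_linenos.append(lineno)
    if file_role is not None and file_role != role:
        raise ValidationError(
            f"{path}: file declares role={file_role!r} but role={role!r} was requested"
        )
    if len(body) < 2:
        raise FormatError(f"{path}: expected a header row and at least one data row")
    try:
        df = pd.read_csv(io.StringIO("".join(body)), index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: could not parse delimited table: {exc}") from exc
    try:
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError):
        for i, (_, row) in enumerate(df.iterrows()):
            try:
                row.astype(float)
            except (ValueError, TypeError):
                raise FormatError(
                    f"{path}, line {body_linenos[i + 1]}: non-numeric value in row "
                    f"{df.index[i]!r}"
                ) from None
        raise FormatError(f"{path}: non-numeric table body") from None
    return _ROLE_BUILDERS[role](values, list(df.index), list(df.columns))


# ---------------------------------------------------------------------------
# protein-wise normalization

def l2_normalize_rows(values: np.ndarray) -> np.ndarray:
    """Scale each nonzero row of ``values`` to unit L2 norm (zero rows kept)."""
    arr = np.asarray(values, dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    return arr / safe[:, None]


def l2_normalize_proteins(X: ExpressionMatrix) -> ExpressionMatrix:
    """Protein-wise L2 normalization: every nonzero protein row gets norm 1.

    This is the ``wt = 1`` limit of the titration blend; it equalizes the
    per-protein "vector size" the way a perfectly titrated antibody panel
    equalizes staining intensity. Zero rows (markers absent from the ROI)
    are left at zero and reported via a warning.
    """
    norms = np.linalg.norm(X.values, axis=1)
    zero = norms == 0
    if zero.any():
        names = [X.protein_ids[i] for i in np.nonzero(zero)[0]]
        warnings.warn(
            f"protein rows with zero norm left unchanged: {', '.join(names)}",
            stacklevel=2,
        )
    return ExpressionMatrix(l2_normalize_rows(X.values), X.protein_ids, X.cell_ids)


def weighted_normalize(X: ExpressionMatrix, spec: NormalizationSpec) -> ExpressionMatrix:
    """Blend raw and protein-normalized expression: wt*X1 + (1-wt)*X.

    With wt = 0 the data are untouched; with wt = 1 every protein has unit
    row norm.  Intermediate weights emulate partially titrated antibody
    concentrations.
    """
    if not isinstance(spec, NormalizationSpec):
        spec = NormalizationSpec(spec)
    if spec.wt == 0.0:
        return ExpressionMatrix(X.values.copy(), X.protein_ids, X.cell_ids)
    x1 = l2_normalize_proteins(X)
    blended = spec.wt * x1.values + (1.0 - spec.wt) * X.values
    return ExpressionMatrix(blended, X.protein_ids, X.cell_ids)
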