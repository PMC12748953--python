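"""Ground-truth data generator with the structure compressed sensing assumes.

Real multiplexed-imaging panels exhibit modular co-expression: a marker
panel decomposes into recurring cell-type signatures (modules), and any one
cell expresses only a few of them.  The generator emulates exactly that:

* a ground-truth dictionary of sparse, unit-norm, nonnegative modules with
  pairwise distinct protein supports;
* cells drawing 1..``modules_per_cell_max`` modules with gamma-distributed
  activities, using tissue-specific module-usage probabilities drawn from a
  Dirichlet so cell-type abundance varies between tissues;
* per-protein intensity scaling (emulating antibody titration differences),
  multiplicative lognormal noise with a chosen coefficient of variation, and
  an optional additive background.

It is an emulation of the data's statistical shape, not of mass-cytometry
physics — no Poisson ion-count statistics, no channel spillover.  A small
renderer turns an expression table into a disk-per-cell image plus label
mask (optionally with injected hot pixels) for exercising the image path.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .core import Dictionary, ExpressionMatrix, ModuleActivity, ValidationError
from .image import CellMask, ImageStack

__all__ = [
    "GeneratorConfig",
    "generate_truth_dictionary",
    "generate_cells",
    "generate_dataset",
    "generate_study",
    "render_image_fixture",
]


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic expression data.

    noise_cv is the coefficient of variation of the multiplicative lognormal
    noise (0.1 ~ 10% intensity jitter); titration_scale_range bounds the
    uniform per-protein intensity multipliers; background_rate is a constant
    additive offset in the same intensity units (default 0: clean modular
    signal).
    """

    p: int = 16
    d_true: int = 10
    modules_per_cell_max: int = 2
    n_cells: int = 2000
    n_tissues: int = 3
    abundance_dirichlet_alpha: float = 1.0
    noise_cv: float = 0.1
    background_rate: float = 0.0
    titration_scale_range: tuple[float, float] = (0.5, 2.0)
    module_size_range: tuple[int, int] = (1, 4)
    activity_shape: float = 2.0
    activity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1 or self.d_true < 1:
            raise ValidationError("p and d_true must be >= 1")
        if self.modules_per_cell_max < 1:
            raise ValidationError("modules_per_cell_max must be >= 1")
        if self.n_cells < 1 or self.n_tissues < 1:
            raise ValidationError("n_cells and n_tissues must be >= 1")
        if self.abundance_dirichlet_alpha <= 0:
            raise ValidationError("abundance_dirichlet_alpha must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be nonnegative")
        if self.background_rate < 0:
            raise ValidationError("background_rate must be nonnegative")
        lo, hi = self.titration_scale_range
        if not (0 < lo <= hi):
            raise ValidationError("titration_scale_range must satisfy 0 < low <= high")
        slo, shi = self.module_size_range
        if not (1 <= slo <= shi):
            raise ValidationError("module_size_range must satisfy 1 <= low <= high")


def generate_truth_dictionary(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> Dictionary:
    """Sparse nonnegative unit-norm modules with pairwise distinct supports.

    Every protein belongs to at least one module: a panel only carries
    markers that are expressed in some cell type, and a protein outside all
    modules would be unrecoverable by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p, d = config.p, config.d_true
    slo = min(config.module_size_range[0], p)
    shi = min(config.module_size_range[1], p)
    n_supports = sum(comb(p, s) for s in range(slo, shi + 1))
    if d > n_supports:
        raise ValidationError(
            f"d_true={d} exceeds the {n_supports} distinct supports available "
            f"for p={p} proteins with sizes in [{slo}, {shi}]"
        )
    if d * shi < p:
        raise ValidationError(
            f"{d} modules of at most {shi} proteins cannot cover all {p} proteins"
        )
    for _ in range(10_000):
        sizes = rng.integers(slo, shi + 1, size=d)
        while sizes.sum() < p:  # need enough slots to cover every protein
            grow = np.nonzero(sizes < shi)[0]
            sizes[rng.choice(grow)] += 1
        # deal a permutation of all proteins into the slots first (coverage),
        # then fill remaining slots with proteins new to that module
        slots: list[list[int]] = [[] for _ in range(d)]
        order = rng.permutation(p).tolist()
        bins = rng.permutation(np.repeat(np.arange(d), sizes))[: len(order)]
        retry = False
        for protein, j in zip(order, bins):
            slots[j].append(protein)
        for j in range(d):
            while len(slots[j]) < sizes[j]:
                candidates = np.setdiff1d(np.arange(p), slots[j])
                slots[j].append(int(rng.choice(candidates)))
        supports = [frozenset(s) for s in slots]
        if len(set(supports)) == d and all(len(s) == n for s, n in zip(supports, sizes)):
            break
        retry = True
    if retry:  # pragma: no cover - combinatorially exhausted
        raise ValidationError("could not sample distinct covering module supports")
    U = np.zeros((p, d))
    for j, support in enumerate(supports):
        idx = sorted(support)
        loadings = rng.uniform(0.5, 1.5, size=len(idx))
        U[idx, j] = loadings / np.linalg.norm(loadings)
    return Dictionary(U, [f"p{i}" for i in range(p)], [f"m{j}" for j in range(d)])


def generate_cells(
    U_true: Dictionary,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    scales: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, ModuleActivity, list[str]]:
    """Sample cells as sparse module combinations and corrupt realistically.

    Returns the observed expression (after titration scaling, lognormal
    noise and background), the ground-truth activities, and per-cell tissue
    labels.  ``scales`` fixes the per-protein titration multipliers; pass
    the same vector to several draws to emulate repeated staining with one
    antibody panel (they are a property of the panel, not of the tissue).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p, d = U_true.values.shape
    n, t = config.n_cells, config.n_tissues
    # near-equal tissue sizes
    sizes = np.full(t, n // t)
    sizes[: n % t] += 1
    W = np.zeros((d, n))
    labels: list[str] = []
    col = 0
    for tissue in range(t):
        probs = rng.dirichlet(np.full(d, config.abundance_dirichlet_alpha))
        for _ in range(sizes[tissue]):
            n_mod = int(rng.integers(1, config.modules_per_cell_max + 1))
            n_mod = min(n_mod, d)
            chosen = rng.choice(d, size=n_mod, replace=False, p=probs)
            W[chosen, col] = rng.gamma(
                config.activity_shape, config.activity_scale, size=n_mod
            )
            labels.append(f"tissue{tissue}")
            col += 1
    X = U_true.values @ W
    if scales is None:
        lo, hi = config.titration_scale_range
        scales = rng.uniform(lo, hi, size=p) if hi > lo else np.full(p, lo)
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (p,) or (scales <= 0).any():
        raise ValidationError(f"scales must be {p} positive multipliers")
    X = X * scales[:, None]
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        # mean-one multiplicative noise
        X = X * rng.lognormal(-0.5 * sigma**2, sigma, size=X.shape)
    if config.background_rate > 0:
        X = X + config.background_rate
    cell_ids = [f"c{i}" for i in range(n)]
    return (
        ExpressionMatrix(X, U_true.protein_ids, cell_ids),
        ModuleActivity(W, U_true.module_ids, cell_ids),
        labels,
    )


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, ModuleActivity, Dictionary, list[str]]:
    """One call: dictionary + cells from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    U = generate_truth_dictionary(config, rng)
    X, W, labels = generate_cells(U, config, rng)
    return X, W, U, labels


def generate_study(
    config: GeneratorConfig, n_draws: int = 2
) -> tuple[Dictionary, np.ndarray, list[tuple[ExpressionMatrix, ModuleActivity, list[str]]]]:
    """Several independent cell draws from one shared antibody panel.

    The ground-truth dictionary and the per-protein titration scales are
    drawn once (they describe the marker panel and antibody mix) and reused
    for every draw, while cells, noise and tissue composition are drawn
    fresh — the setting of training a dictionary on one experiment and
    decompressing another.  Cell ids are prefixed per draw to stay unique.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = np.random.default_rng(config.seed)
    U_true = generate_truth_dictionary(config, rng)
    lo, hi = config.titration_scale_range
    scales = rng.uniform(lo, hi, size=config.p) if hi > lo else np.full(config.p, lo)
    draws = []
    for k in range(n_draws):
        X, W, labels = generate_cells(U_true, config, rng, scales=scales)
        cell_ids = [f"d{k}_{cid}" for cid in X.cell_ids]
        draws.append(
            (
                ExpressionMatrix(X.values, X.protein_ids, cell_ids),
                ModuleActivity(W.values, W.module_ids, cell_ids),
                labels,
            )
        )
    return U_true, scales, draws


# ---------------------------------------------------------------------------
# image fixture rendering

def render_image_fixture(
    X: ExpressionMatrix,
    image_size: tuple[int, int] = (64, 64),
    cell_radius: int = 3,
    n_hot_pixels: int = 0,
    hot_value: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, CellMask, list[tuple[int, int, int]]]:
    """Draw each cell as a uniform disk; return stack, mask, hot-pixel coords.

    Cells are placed on a regular grid of non-overlapping disks, so
    aggregating the clean stack over the mask returns ``X`` exactly.  Hot
    pixels (value ``hot_value``, default well above the image maximum) are
    injected at recorded (channel, row, col) positions for filter tests.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    h, w = image_size
    step = 2 * cell_radius + 2
    rows = h // step
    cols = w // step
    if rows * cols < X.n_cells:
        raise ValidationError(
            f"canvas {image_size} fits {rows * cols} disks of radius "
            f"{cell_radius}, need {X.n_cells}"
        )
    pixels = np.zeros((X.n_proteins, h, w))
    mask = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.ogrid[:h, :w]
    for k in range(X.n_cells):
        cy = (k // cols) * step + cell_radius + 1
        cx = (k % cols) * step + cell_radius + 1
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius**2
        mask[disk] = k + 1
        pixels[:, disk] = X.values[:, [k]]
    hot_coords: list[tuple[int, int, int]] = []
    if n_hot_pixels > 0:
        if hot_value is None:
            hot_value = float(pixels.max()) * 10.0 + 1000.0
        for _ in range(n_hot_pixels):
            c = int(rng.integers(X.n_proteins))
            r = int(rng.integers(h))
            q = int(rng.integers(w))
            pixels[c, r, q] = hot_value
            hot_coords.append((c, r, q))
    return (
        ImageStack(pixels, X.protein_ids),
        CellMask(mask),
        hot_coords,
    )
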