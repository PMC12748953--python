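"""Image-level preprocessing for ion-count images.

Two hot-pixel filters and mask-based aggregation turn multichannel ion-count
images plus an integer cell mask into a single-cell expression table.  Hot
pixels — isolated spuriously bright pixels typical of mass-cytometry
ablation — are detected per channel as pixels exceeding the maximum of their
8-neighborhood by more than a threshold.  The ``clip`` filter replaces the
hot pixel with that neighborhood maximum; the ``min_propagate`` filter
instead writes the neighborhood *minimum* to the hot pixel and all eight
neighbors, which suppresses halos around strong spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .core import ExpressionMatrix, ValidationError, _check_ids

__all__ = [
    "ImageStack",
    "CellMask",
    "filter_hot_pixels_clip",
    "filter_hot_pixels_min_propagate",
    "aggregate_by_mask",
    "sum_channels",
    "read_image_stack",
    "write_image_stack",
    "read_cell_mask",
    "write_cell_mask",
]

# 8-neighborhood footprints (center excluded / included)
_RING = np.ones((3, 3), dtype=bool)
_RING[1, 1] = False
_FULL = np.ones((3, 3), dtype=bool)


@dataclass
class ImageStack:
    """Nonnegative channels x height x width pixel array with channel ids."""

    pixels: np.ndarray
    channel_ids: Sequence[str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise ValidationError(f"image stack must be 3-D, got ndim={arr.ndim}")
        if arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValidationError("image height and width must be >= 1")
        if not np.isfinite(arr).all():
            raise ValidationError("image stack contains NaN or Inf")
        if (arr < 0).any():
            raise ValidationError("image stack contains negative pixel values")
        self.pixels = arr
        self.channel_ids = _check_ids(self.channel_ids, arr.shape[0], "channel_ids")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass
class CellMask:
    """Integer label image; 0 is background, label k > 0 marks cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValidationError(f"cell mask must be 2-D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            as_int = arr.astype(np.int64)
            if not np.array_equal(as_int, arr):
                raise ValidationError("cell mask labels must be integers")
            arr = as_int
        if (arr < 0).any():
            raise ValidationError("cell mask labels must be nonnegative")
        self.labels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_labels(self) -> np.ndarray:
        """Distinct nonzero labels in ascending order."""
        labels = np.unique(self.labels)
        return labels[labels > 0]


def _neighbor_max(img: np.ndarray) -> np.ndarray:
    """Max over the in-image 8-neighborhood of each pixel (center excluded)."""
    return ndimage.maximum_filter(img, footprint=_RING, mode="constant", cval=-np.inf)


def _neighbor_min(img: np.ndarray) -> np.ndarray:
    """Min over the in-image 8-neighborhood of each pixel (center excluded)."""
    return ndimage.minimum_filter(img, footprint=_RING, mode="constant", cval=np.inf)


def _hot_mask(img: np.ndarray, threshold: float) -> np.ndarray:
    nbmax = _neighbor_max(img)
    # a 1x1 image has an empty neighborhood; nothing to compare against
    return np.isfinite(nbmax) & (img - nbmax > threshold)


def filter_hot_pixels_clip(stack: ImageStack, threshold: float = 50.0) -> ImageStack:
    """Clip hot pixels to the maximum of their 8-neighborhood.

    Per channel, a pixel is hot iff its value exceeds the maximum of its
    in-image 8-neighborhood by more than ``threshold``; hot pixels take that
    maximum, all other pixels are untouched.  Never increases any pixel.
    """
    if threshold < 0:
        raise ValidationError("hot-pixel threshold must be nonnegative")
    out = stack.pixels.copy()
    for c in range(stack.n_channels):
        img = stack.pixels[c]
        hot = _hot_mask(img, threshold)
        if hot.any():
            out[c][hot] = _neighbor_max(img)[hot]
    return ImageStack(out, stack.channel_ids)


def filter_hot_pixels_min_propagate(
    stack: ImageStack, threshold: float = 50.0
) -> ImageStack:
    """Replace each hot pixel and its 8 neighbors by the neighborhood minimum.

    Detection is identical to :func:`filter_hot_pixels_clip` and runs in a
    single pass on the input image.  For each hot pixel the minimum of its
    in-image 8-neighborhood is written to the pixel itself and its eight
    neighbors; where writes from adjacent hot pixels overlap, or where a
    neighbor is already darker, the minimum wins, so the filter never
    increases any pixel and is independent of scan order.
    """
    if threshold < 0:
        raise ValidationError("hot-pixel threshold must be nonnegative")
    out = stack.pixels.copy()
    for c in range(stack.n_channels):
        img = stack.pixels[c]
        hot = _hot_mask(img, threshold)
        if not hot.any():
            continue
        vmap = np.full_like(img, np.inf)
        vmap[hot] = _neighbor_min(img)[hot]
        # dilate each hot pixel's replacement value onto its 3x3 block,
        # resolving overlaps to the minimum competing value
        candidate = ndimage.minimum_filter(
            vmap, footprint=_FULL, mode="constant", cval=np.inf
        )
        out[c] = np.minimum(img, candidate)
    return ImageStack(out, stack.channel_ids)


def aggregate_by_mask(stack: ImageStack, mask: CellMask) -> ExpressionMatrix:
    """Mean pixel intensity per channel within each labeled cell region.

    Output rows are channels, columns are cells in ascending label order with
    stringified labels as cell ids.
    """
    if stack.shape != mask.shape:
        raise ValidationError(
            f"image shape {stack.shape} does not match mask shape {mask.shape}"
        )
    labels = mask.cell_labels()
    if labels.size == 0:
        raise ValidationError("no cells in mask")
    values = np.empty((stack.n_channels, labels.size))
    for c in range(stack.n_channels):
        values[c] = ndimage.mean(stack.pixels[c], labels=mask.labels, index=labels)
    return ExpressionMatrix(values, stack.channel_ids, [str(l) for l in labels])


def sum_channels(stack: ImageStack, channel_subset: Sequence[str]) -> ImageStack:
    """Pixelwise sum of a subset of channels as a single-channel stack.

    Used e.g. to pool cytoplasmic marker channels into one segmentation input.
    """
    subset = list(channel_subset)
    if not subset:
        raise ValidationError("channel subset must be nonempty")
    index = {cid: i for i, cid in enumerate(stack.channel_ids)}
    unknown = [cid for cid in subset if cid not in index]
    if unknown:
        raise ValidationError(f"unknown channel ids: {', '.join(map(str, unknown))}")
    rows = [index[cid] for cid in subset]
    summed = stack.pixels[rows].sum(axis=0, keepdims=True)
    return ImageStack(summed, ["+".join(subset)])


# ---------------------------------------------------------------------------
# TIFF I/O

def read_image_stack(path, channel_ids: Sequence[str] | None = None) -> ImageStack:
    arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(arr.shape[0])]
    return ImageStack(arr, channel_ids)


def write_image_stack(path, stack: ImageStack) -> None:
    tifffile.imwrite(path, stack.pixels.astype(np.float32))


def read_cell_mask(path) -> CellMask:
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    return CellMask(np.asarray(arr))


def write_cell_mask(path, mask: CellMask) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32))
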