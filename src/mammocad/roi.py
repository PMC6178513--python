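"""Sparse region-of-interest patches.

A :class:`SparseROI` is a rectangular crop of a mammogram in which every
pixel outside the segmented mass support is *exactly* zero, so the patch
is a sparse matrix whose nonzero structure encodes the (irregular) mass
shape.  The smallest patch the pipeline accepts is 25 x 22 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Minimum ROI shape (rows, cols) accepted by the descriptor stage.
MIN_ROI_SHAPE: tuple[int, int] = (25, 22)


@dataclass
class SparseROI:
    """A bounding-box patch with non-mass pixels set exactly to zero.

    Parameters
    ----------
    pixels
        2-D float array in ``[0, 1]``; zeros mark background.
    bbox
        Half-open ``(row0, col0, row1, col1)`` bounding box in the source
        image, if the ROI was extracted from one.
    group
        Identifier of the source image / source ROI, used to keep augmented
        copies of the same patch inside a single cross-validation fold.
    """

    pixels: np.ndarray
    bbox: tuple[int, int, int, int] | None = None
    group: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("SparseROI pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("SparseROI pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean support of the mass (nonzero pixels)."""
        return self.pixels != 0

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.pixels))


def pad_to_min(pixels: np.ndarray,
               min_shape: tuple[int, int] = MIN_ROI_SHAPE) -> np.ndarray:
    """Zero-pad a patch symmetrically up to ``min_shape``.

    The extra row/column for odd deficits goes to the bottom/right.
    """
    h, w = pixels.shape
    dh = max(min_shape[0] - h, 0)
    dw = max(min_shape[1] - w, 0)
    if dh == 0 and dw == 0:
        return pixels
    return np.pad(pixels, ((dh // 2, dh - dh // 2), (dw // 2, dw - dw // 2)))


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check the grayscale-image contract: 2-D, finite, values in [0, 1]."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    if img.size and (img.min() < 0 or img.max() > 1):
        raise ValueError(f"{name} values must lie in [0, 1]")
    return img
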