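"""Contrast enhancement and breast-field cleanup.

The enhancement stage fuses the original mammogram with its CLAHE
(contrast-limited adaptive histogram equalization) version by a local
entropy-maximization rule: at every pixel the fused image takes the value
from whichever source shows the larger Shannon entropy

    ENT = -sum_k p_k log2 p_k,      k = 0..255,

computed over the 256-bin histogram of a small (default 5 x 5) window
centered at the pixel.  High local entropy marks the source that carries
more local detail there; ties keep the original value so flat regions are
not replaced by CLAHE noise.

The module also provides a breast mask (Otsu threshold, largest connected
component, holes filled) and a simple pectoral-muscle suppressor that
fits a straight line to per-row maximum-gradient points inside the top
corner rectangle and zeroes everything above it.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, stats
from skimage import exposure, filters, measure

from .roi import validate_image

__all__ = [
    "clahe",
    "local_entropy",
    "entropy_fusion",
    "breast_mask",
    "remove_pectoral",
]


def clahe(img: np.ndarray, clip_limit: float = 0.01,
          tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, output in [0, 1]."""
    img = validate_image(img)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    if tiles[0] < 1 or tiles[1] < 1:
        raise ValueError("need at least one tile per axis")
    if img.max() == img.min():  # nothing to redistribute
        return img.copy()
    kernel = (max(img.shape[0] // tiles[0], 1), max(img.shape[1] // tiles[1], 1))
    out = exposure.equalize_adapthist(img, kernel_size=kernel,
                                      clip_limit=clip_limit, nbins=256)
    return np.clip(out, 0.0, 1.0)


def local_entropy(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of the local 256-level histogram.

    The image is quantized to 256 gray levels; for each pixel the
    ``window x window`` neighborhood (borders reflected) is histogrammed
    and ``-sum p_k log2 p_k`` evaluated with ``0 log 0 := 0``.  Values lie
    in ``[0, log2(window^2)]``.
    """
    img = validate_image(img)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    q = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    ent = np.zeros(img.shape, dtype=float)
    for level in np.unique(q):
        p = ndimage.uniform_filter((q == level).astype(float), size=window,
                                   mode="reflect")
        np.clip(p, 0.0, 1.0, out=p)
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    return np.clip(ent, 0.0, np.log2(window * window))


def entropy_fusion(orig: np.ndarray, enhanced: np.ndarray,
                   window: int = 5) -> np.ndarray:
    """Per-pixel maximum-local-entropy fusion of two registered images.

    Each output pixel is copied from whichever input has the larger local
    entropy at that position; ties take the original image's value.
    """
    orig = validate_image(orig, "orig")
    enhanced = validate_image(enhanced, "enhanced")
    if orig.shape != enhanced.shape:
        raise ValueError("images must share a shape")
    ent_o = local_entropy(orig, window)
    ent_e = local_entropy(enhanced, window)
    return np.where(ent_e > ent_o, enhanced, orig)


def enhance(img: np.ndarray, clip_limit: float = 0.01,
            tiles: tuple[int, int] = (8, 8), window: int = 5) -> np.ndarray:
    """Full enhancement: fuse the image with its CLAHE version."""
    return entropy_fusion(img, clahe(img, clip_limit, tiles), window)


def breast_mask(img: np.ndarray) -> np.ndarray:
    """Binary breast-field mask.

    Otsu threshold, then the largest 8-connected foreground component
    with holes filled.  Raises on an all-zero image.
    """
    img = validate_image(img)
    if not np.any(img > 0):
        raise ValueError("cannot build a breast mask from an all-zero image")
    thresh = filters.threshold_otsu(img)
    fg = img > thresh
    if not fg.any():
        fg = img > 0
    labels = measure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def _detect_side(img: np.ndarray) -> str:
    h, w = img.shape
    top = img[: h // 3]
    return "left" if top[:, : w // 2].sum() >= top[:, w // 2:].sum() else "right"


def remove_pectoral(img: np.ndarray, side: str | None = None, *,
                    row_frac: float = 0.4, col_frac: float = 0.5,
                    min_gradient: float = 0.1) -> np.ndarray:
    """Suppress the pectoral muscle in an MLO-style image.

    Within the top-corner rectangle (top ``row_frac`` of rows, the
    ``col_frac`` of columns nearest the pectoral side) the column of
    maximum horizontal-gradient magnitude is located per row; a straight
    line is least-squares fitted through those points and all pixels on
    the muscle side of the line are zeroed.  Rows whose best gradient is
    weaker than ``min_gradient`` are ignored; if fewer than 3 strong rows
    remain the image is returned unchanged with a warning.
    """
    img = validate_image(img)
    h, w = img.shape
    if side is None:
        side = _detect_side(img)
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")

    work = img if side == "left" else img[:, ::-1]
    n_rows = max(int(row_frac * h), 3)
    n_cols = max(int(col_frac * w), 3)
    grad = np.abs(ndimage.sobel(work, axis=1, mode="reflect")) / 8.0
    # only look for the boundary well inside the breast, so the skin-air
    # edge never masquerades as a pectoral edge
    interior = ndimage.binary_erosion(work > 0, iterations=4)
    region = np.where(interior[:n_rows, :n_cols], grad[:n_rows, :n_cols], 0.0)
    best_col = np.argmax(region, axis=1)
    strength = region[np.arange(n_rows), best_col]
    keep = strength >= min_gradient
    rows = np.nonzero(keep)[0]
    # a real pectoral edge crosses most rows of the rectangle and the
    # points fall on a straight line; mass borders or texture do neither
    if keep.sum() < max(5, 0.3 * n_rows):
        warnings.warn("no pectoral boundary found; image returned unchanged",
                      stacklevel=2)
        return img.copy()
    # robust line fit: Theil-Sen start (immune to mass-border outliers),
    # then least squares on the inliers; a genuine straight boundary keeps
    # most rows, scattered points do not
    slope = stats.theilslopes(best_col[rows], rows).slope
    intercept = float(np.median(best_col[rows] - slope * rows))
    inl = np.abs(best_col[rows] - (slope * rows + intercept)) < 4.0
    if inl.sum() < max(5, 0.3 * n_rows):
        warnings.warn("gradient points not collinear; image returned unchanged",
                      stacklevel=2)
        return img.copy()
    sel = rows[inl]
    slope, intercept = np.polyfit(sel, best_col[sel], 1)

    rr, cc = np.indices((h, w))
    boundary = slope * rr + intercept
    cut = (cc < boundary + 1.5) & (rr < n_rows * 1.05)
    out = work.copy()
    out[cut] = 0.0
    return out if side == "left" else out[:, ::-1]
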