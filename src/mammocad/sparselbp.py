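"""Sparse uniform local binary patterns over curvelet subbands.

This is the descriptor at the heart of the false-positive reduction
stage.  A candidate patch is a sparse matrix — pixels off the mass
support are exactly zero — and so are its curvelet subband coefficient
maps (up to a small tolerance).  Instead of evaluating LBP codes at every
position, a lookup table of 3 x 3 sliding windows first classifies each
fully-interior window center as *foreground* (more than 2 nonzero values
in the window) or *background* (rejected); uniform LBP codes with P = 8
neighbors at radius R = 1 are then computed only at foreground centers.

A pattern is *uniform* when its circular bit string has at most two
0<->1 transitions (wrap-around included); exactly 58 = P(P-1)+2 such
patterns exist for P = 8.  Non-uniform codes are discarded and the
58-bin histogram is normalized by the number of retained codes.  Running
this on each of the 17 curvelet subbands of a patch and concatenating
gives the 17 x 58 = 986-dimensional feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fdct import fdct_forward, subband_list
from .roi import MIN_ROI_SHAPE, SparseROI

__all__ = [
    "NONUNIFORM",
    "N_BINS",
    "N_FEATURES",
    "uniform_codebook",
    "ulbp_code",
    "LookupTable",
    "build_lookup",
    "LBPHistogram",
    "sparse_lbp_hist",
    "spatial_sparse_lbp",
    "describe_roi",
    "sparse_subbands",
    "reduction_stats",
    "roi_reduction_stats",
]

#: Sentinel bin for patterns with more than two circular transitions.
NONUNIFORM = -1
#: Number of uniform patterns for P = 8: P*(P-1) + 2.
N_BINS = 58
#: Descriptor length: 17 subbands x 58 bins.
N_FEATURES = 986

# ring neighbors counter-clockwise from the east neighbor, (drow, dcol)
_RING = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def _transitions(code: int, p: int = 8) -> int:
    count = 0
    for i in range(p):
        if ((code >> i) & 1) != ((code >> ((i + 1) % p)) & 1):
            count += 1
    return count


def uniform_codebook(p: int = 8) -> dict[int, int]:
    """Map each uniform pattern value to a histogram bin 0..57.

    Bins are assigned in ascending pattern order; there are exactly
    ``p*(p-1) + 2`` uniform patterns.
    """
    patterns = [c for c in range(1 << p) if _transitions(c, p) <= 2]
    assert len(patterns) == p * (p - 1) + 2
    return {c: i for i, c in enumerate(patterns)}


_CODEBOOK = uniform_codebook(8)
# dense 256 -> bin lookup; NONUNIFORM for the rest
_BIN_OF = np.full(256, NONUNIFORM, dtype=np.int64)
for _pat, _bin in _CODEBOOK.items():
    _BIN_OF[_pat] = _bin


def ulbp_code(window: np.ndarray) -> int:
    """Uniform-LBP bin of a 3 x 3 window, or :data:`NONUNIFORM`.

    Bit p is set when the p-th ring neighbor (counter-clockwise from the
    east neighbor) is >= the center value; the sign function treats ties
    as 1.
    """
    window = np.asarray(window, dtype=float).reshape(3, 3)
    center = window[1, 1]
    code = 0
    for p, (dr, dc) in enumerate(_RING):
        if window[1 + dr, 1 + dc] >= center:
            code |= 1 << p
    return int(_BIN_OF[code])


@dataclass
class LookupTable:
    """Per-window bookkeeping for foreground selection.

    One row per fully-interior 3 x 3 window, row-major: the center
    location, the 9 window values, the count of nonzero values and the
    foreground flag (count > 2).
    """

    centers: np.ndarray      # (K, 2) int
    windows: np.ndarray      # (K, 9)
    nonzero_count: np.ndarray  # (K,) int
    foreground: np.ndarray   # (K,) bool

    def __len__(self) -> int:
        return self.centers.shape[0]


def _window_view(band: np.ndarray) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(band, (3, 3))


def build_lookup(band: np.ndarray, tol: float = 0.0) -> LookupTable:
    """Classify every interior 3 x 3 window as foreground or background.

    A value is "nonzero" when ``|value| > tol``.  A window with more than
    2 nonzero values is foreground (an LBP code will be computed there);
    windows with 2 or fewer are background and are rejected.
    """
    band = np.asarray(band, dtype=float)
    if band.ndim != 2 or band.shape[0] < 3 or band.shape[1] < 3:
        raise ValueError("band must be a 2-D array of at least 3 x 3")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    view = _window_view(band)
    h, w = view.shape[:2]
    windows = view.reshape(h * w, 9)
    counts = (np.abs(windows) > tol).sum(axis=1)
    rr, cc = np.mgrid[1:h + 1, 1:w + 1]
    return LookupTable(centers=np.stack([rr.ravel(), cc.ravel()], axis=1),
                       windows=windows.copy(),
                       nonzero_count=counts.astype(np.int64),
                       foreground=counts > 2)


@dataclass
class LBPHistogram:
    """Normalized 58-bin uniform-LBP histogram of one band."""

    bins: np.ndarray
    n_foreground: int

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_BINS,):
            raise ValueError(f"histogram must have {N_BINS} bins")


def _codes(band: np.ndarray) -> np.ndarray:
    """Vectorized LBP codes (0..255) for all interior centers."""
    center = band[1:-1, 1:-1]
    code = np.zeros(center.shape, dtype=np.int64)
    for p, (dr, dc) in enumerate(_RING):
        nb = band[1 + dr: band.shape[0] - 1 + dr, 1 + dc: band.shape[1] - 1 + dc]
        code |= (nb >= center).astype(np.int64) << p
    return code


def sparse_lbp_hist(band: np.ndarray, tol: float = 0.0) -> LBPHistogram:
    """Uniform-LBP histogram computed only at foreground window centers.

    Foreground selection follows :func:`build_lookup` (> 2 nonzero values
    in the 3 x 3 window); the LBP comparison itself uses the full window,
    background neighbors included.  Non-uniform codes are discarded; the
    histogram is normalized by the number of retained codes and is
    all-zero when nothing is retained.
    """
    band = np.asarray(band, dtype=float)
    if band.ndim != 2 or band.shape[0] < 3 or band.shape[1] < 3:
        raise ValueError("band must be a 2-D array of at least 3 x 3")
    nz = (np.abs(band) > tol).astype(np.int64)
    counts = sum(nz[1 + dr: band.shape[0] - 1 + dr,
                    1 + dc: band.shape[1] - 1 + dc]
                 for dr in (-1, 0, 1) for dc in (-1, 0, 1))
    fg = counts > 2
    bins = _BIN_OF[_codes(band)]
    keep = fg & (bins >= 0)
    n_kept = int(keep.sum())
    hist = np.bincount(bins[keep], minlength=N_BINS).astype(float)
    if n_kept:
        hist /= n_kept
    return LBPHistogram(bins=hist, n_foreground=int(fg.sum()))


def spatial_sparse_lbp(roi: SparseROI) -> LBPHistogram:
    """Sparse uniform-LBP histogram of the raw ROI pixels (tol = 0)."""
    if roi.shape[0] < 3 or roi.shape[1] < 3:
        raise ValueError("ROI must be at least 3 x 3")
    return sparse_lbp_hist(roi.pixels, tol=0.0)


def sparse_subbands(roi: SparseROI) -> list[np.ndarray]:
    """The 17 curvelet subbands of an ROI, restricted to the mass support.

    The subbands are full-resolution coefficient maps on the (evenized)
    ROI grid, so the mass support carries over position for position:
    coefficients outside the support are set exactly to zero — they
    describe the zero background, not the mass shape.  These masked maps
    are the "sparse curvelet coefficients" the descriptor is built on,
    and their zero structure is what the lookup-table foreground rule
    exploits; the fraction of rejected windows therefore tracks the shape
    of each individual ROI.
    """
    if roi.shape[0] < MIN_ROI_SHAPE[0] or roi.shape[1] < MIN_ROI_SHAPE[1]:
        raise ValueError(
            f"ROI must be at least {MIN_ROI_SHAPE[0]} x {MIN_ROI_SHAPE[1]}")
    dec = fdct_forward(roi.pixels)
    support = roi.mask
    ph = dec.coarse.shape[0] - support.shape[0]
    pw = dec.coarse.shape[1] - support.shape[1]
    if ph or pw:  # mirror the transform's reflect-padding of odd sizes
        support = np.pad(support, ((0, ph), (0, pw)), mode="symmetric")
    return [np.where(support, band, 0.0) for band in subband_list(dec)]


def describe_roi(roi: SparseROI, tol_rel: float = 1e-6) -> np.ndarray:
    """986-dimensional sparse-curvelet-LBP descriptor of an ROI.

    The ROI is decomposed into 17 support-masked curvelet subbands
    (:func:`sparse_subbands`); each gets a sparse uniform-LBP histogram
    with nonzero tolerance ``tol_rel * max|coefficient|`` of that band
    (guarding against rounding residue), and the 17 histograms are
    concatenated in subband order (coarse first, wedges counter-clockwise).
    """
    if tol_rel < 0:
        raise ValueError("tol_rel must be non-negative")
    parts = []
    for band in sparse_subbands(roi):
        peak = float(np.abs(band).max())
        tol = tol_rel * peak if peak > 0 else 0.0
        parts.append(sparse_lbp_hist(band, tol=tol).bins)
    vec = np.concatenate(parts)
    assert vec.shape == (N_FEATURES,)
    return vec


def reduction_stats(band: np.ndarray, tol: float = 0.0) -> dict[str, float]:
    """Coefficient-reduction bookkeeping for one band.

    Returns the percentage of window rows rejected by the foreground rule
    and the percentage of coefficients that are (tolerance-)zero — the
    two natural measures of how much work the sparse rule saves.
    """
    lut = build_lookup(band, tol)
    n = len(lut)
    rejected_rows = 100.0 * float((~lut.foreground).sum()) / n if n else 0.0
    zero_coeff = 100.0 * float((np.abs(band) <= tol).sum()) / band.size
    return {"window_reduction_pct": rejected_rows,
            "coefficient_reduction_pct": zero_coeff}


def roi_reduction_stats(roi: SparseROI, tol_rel: float = 1e-6) -> dict[str, float]:
    """Aggregate coefficient reduction across all 17 subbands of an ROI.

    Reports how many lookup-table rows the foreground rule rejects and how
    many coefficients are zero, both as percentages of the totals over the
    whole decomposition; shape-dependent, as every ROI's support differs.
    """
    rej_rows = rows = zero = size = 0
    for band in sparse_subbands(roi):
        peak = float(np.abs(band).max())
        tol = tol_rel * peak if peak > 0 else 0.0
        lut = build_lookup(band, tol)
        rej_rows += int((~lut.foreground).sum())
        rows += len(lut)
        zero += int((np.abs(band) <= tol).sum())
        size += band.size
    return {"window_reduction_pct": 100.0 * rej_rows / rows,
            "coefficient_reduction_pct": 100.0 * zero / size}
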