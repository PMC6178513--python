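"""Fast discrete curvelet transform (frequency-wedge tiling).

The transform tiles the 2-D FFT plane into 1 + 16 = 17 subbands: a
low-pass square corona (the coarse band) and one detail corona split into
16 angular wedges.  The radial split uses Meyer-type raised-cosine
windows of the max-norm radius (a *square* corona with its inner boundary
at half the Nyquist square); the angular split uses raised-cosine
crossfades of the orientation angle taken modulo pi, so each wedge window
pairs every direction with its antipodal partner and the spatial
coefficients come out real (the real-transform convention: 16 wedges
cover 180 degrees of orientations).

All window functions are non-negative and their squares sum to one at
every frequency, so the transform is a tight frame: the adjoint is the
exact inverse and total coefficient energy equals image energy.
Subbands are kept at full resolution (no wedge wrapping / decimation),
which trades memory for an exactly invertible, aliasing-free transform —
the descriptor stage only needs per-subband coefficient maps.

Odd image dimensions are reflect-padded to even before the FFT; the
inverse crops back to the source shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "WedgeGeometry",
    "CurveletDecomposition",
    "fdct_forward",
    "fdct_inverse",
    "subband_list",
]

#: Minimum accepted input shape (rows, cols).
MIN_SHAPE = (25, 22)

N_ANGLES = 16
#: Inner radial boundary of the detail corona (fraction of the Nyquist square).
R_SPLIT = 0.5


@dataclass(frozen=True)
class WedgeGeometry:
    """Frequency support of one subband.

    Radial bounds are fractions of the Nyquist square (max-norm radius);
    angular bounds are radians modulo pi (None for the coarse band).
    Adjacent supports overlap inside the raised-cosine transition zones.
    """

    kind: str                      # "coarse" | "wedge"
    r_low: float
    r_high: float
    theta_center: float | None = None
    theta_halfwidth: float | None = None


@dataclass
class CurveletDecomposition:
    """1 coarse + 16 angular-wedge subbands of a real image."""

    coarse: np.ndarray
    wedges: list[np.ndarray]
    geometry: list[WedgeGeometry]
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.wedges) != N_ANGLES:
            raise ValueError(f"expected {N_ANGLES} wedge subbands")


def _meyer_ramp(t: np.ndarray) -> np.ndarray:
    """Smooth 0->1 ramp on [0, 1] (Meyer auxiliary polynomial)."""
    t = np.clip(t, 0.0, 1.0)
    return t ** 4 * (35.0 - 84.0 * t + 70.0 * t ** 2 - 20.0 * t ** 3)


@lru_cache(maxsize=32)
def _windows(shape: tuple[int, int], angles: int) -> np.ndarray:
    """The 1 + angles frequency windows U_b; sum_b U_b^2 == 1 everywhere."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None] * 2.0   # in [-1, 1): fraction of Nyquist
    fx = np.fft.fftfreq(w)[None, :] * 2.0
    r = np.maximum(np.abs(fy), np.abs(fx))          # square (max-norm) radius
    theta = np.mod(np.arctan2(np.broadcast_to(fy, (h, w)),
                              np.broadcast_to(fx, (h, w))), np.pi)

    # radial split: low-pass flat below R_SPLIT/2, cosine ramp to R_SPLIT
    t = (r - R_SPLIT / 2.0) / (R_SPLIT / 2.0)
    low = np.cos(0.5 * np.pi * _meyer_ramp(t))
    high = np.sqrt(np.clip(1.0 - low ** 2, 0.0, 1.0))

    delta = np.pi / angles
    wins = np.empty((1 + angles, h, w))
    wins[0] = low
    for l in range(angles):
        # distance to wedge center in wedge units, wrapped on [0, pi)
        u = np.mod(theta / delta - l + angles / 2.0, angles) - angles / 2.0
        a = np.where(np.abs(u) < 1.0,
                     np.cos(0.5 * np.pi * _meyer_ramp(np.abs(u))), 0.0)
        wins[1 + l] = high * a

    # Symmetrize under frequency negation so every subband is real.  On the
    # Nyquist row/column (even sizes) -omega aliases onto itself while the
    # orientation angle flips, so the raw angular window is asymmetric
    # there.  Averaging the squared window with its negated copy restores
    # U(-w) = U(w) and leaves sum_b U_b^2 = 1 intact.
    for b in range(1 + angles):
        neg = np.roll(wins[b][::-1, ::-1], (1, 1), axis=(0, 1))
        wins[b] = np.sqrt(0.5 * (wins[b] ** 2 + neg ** 2))
    return wins


def _pad_even(img: np.ndarray) -> np.ndarray:
    ph = img.shape[0] % 2
    pw = img.shape[1] % 2
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="symmetric")
    return img


def fdct_forward(img: np.ndarray, scales: int = 2,
                 angles: int = N_ANGLES) -> CurveletDecomposition:
    """Decompose a real image into 1 coarse + ``angles`` wedge subbands.

    ``scales=2`` (one coarse scale + one detail corona) and ``angles=16``
    are the configuration used throughout the pipeline; the transform is
    linear, real-valued and exactly invertible.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("input must be a 2-D image")
    if img.shape[0] < MIN_SHAPE[0] or img.shape[1] < MIN_SHAPE[1]:
        raise ValueError(
            f"image must be at least {MIN_SHAPE[0]} x {MIN_SHAPE[1]}")
    if scales != 2:
        raise NotImplementedError("only the two-scale configuration is supported")
    source_shape = img.shape
    padded = _pad_even(img)
    wins = _windows(padded.shape, angles)
    spectrum = np.fft.fft2(padded)
    bands = [np.fft.ifft2(wins[b] * spectrum).real for b in range(1 + angles)]

    delta = np.pi / angles
    geometry = [WedgeGeometry("coarse", 0.0, R_SPLIT)]
    for l in range(angles):
        geometry.append(WedgeGeometry("wedge", R_SPLIT / 2.0, 1.0,
                                      theta_center=l * delta,
                                      theta_halfwidth=delta))
    return CurveletDecomposition(coarse=bands[0], wedges=bands[1:],
                                 geometry=geometry, source_shape=source_shape)


def fdct_inverse(dec: CurveletDecomposition) -> np.ndarray:
    """Reconstruct the image; exact up to floating-point rounding."""
    shape = dec.coarse.shape
    if any(w.shape != shape for w in dec.wedges):
        raise ValueError("inconsistent subband shapes")
    wins = _windows(shape, len(dec.wedges))
    acc = wins[0] * np.fft.fft2(dec.coarse)
    for l, band in enumerate(dec.wedges):
        acc += wins[1 + l] * np.fft.fft2(band)
    full = np.fft.ifft2(acc).real
    h, w = dec.source_shape
    return full[:h, :w]


def subband_list(dec: CurveletDecomposition) -> list[np.ndarray]:
    """Coarse band first, then the 16 wedges counter-clockwise from angle 0."""
    return [dec.coarse, *dec.wedges]
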