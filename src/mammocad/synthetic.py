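"""Synthetic mammogram phantoms and sparse ROI generators.

The phantoms emulate the gross structure of a screening mammogram: a
breast half-disc against a zero background, a smooth intensity ramp away
from the chest wall, correlated background texture, an optional bright
pectoral-muscle wedge in the top corner, and one or more bright masses
with irregular, star-perturbed borders.  Mass pixel counts at the default
radii fall inside the pixel-level-threshold (PLT) band used for candidate
filtering, so the full detection pipeline can be exercised end to end
without any real dataset.

Masses are modelled in polar coordinates as

    r(theta) = r0 * (1 + irregularity * sum_{k=2..5} a_k cos(k theta + phi_k))

with the harmonic amplitudes ``a_k`` drawn once per mass.  Low harmonics
(k = 2..5) give the lobulated / ill-defined borders that the sparse
descriptor is designed to capture; ``irregularity = 0`` recovers an exact
ellipse.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .roi import MIN_ROI_SHAPE, SparseROI

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_sparse_roi",
    "make_labeled_roi_set",
    "write_phantom",
    "write_roi_set",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic mammogram phantom.

    Defaults give a 256 x 256 phantom with two masses of 450-2800 pixels
    (inside the 450-31,500 PLT band used for small-format mammograms),
    mass/background contrast 0.4 and mild acquisition noise.
    """

    width: int = 256
    height: int = 256
    n_masses: int = 2
    mass_radius_range: tuple[float, float] = (12.0, 30.0)
    irregularity: float = 0.3
    contrast: float = 0.4
    noise_sigma: float = 0.02
    with_pectoral: bool = False
    pectoral_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("phantom dimensions must be at least 64 x 64")
        if self.n_masses < 0:
            raise ValueError("n_masses must be non-negative")
        lo, hi = self.mass_radius_range
        if not (4 <= lo <= hi):
            raise ValueError("mass radii must satisfy 4 <= lo <= hi")
        if not 0 <= self.irregularity <= 1:
            raise ValueError("irregularity must lie in [0, 1]")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.pectoral_side not in ("left", "right"):
            raise ValueError("pectoral_side must be 'left' or 'right'")


def _star_radius(theta: np.ndarray, irregularity: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Multiplicative radial perturbation; bounded so radius stays positive."""
    amps = rng.uniform(0.5, 1.0, size=4)
    amps *= 0.35 / amps.sum()  # sum |a_k| = 0.35 keeps the factor in [0.65, 1.35]
    phases = rng.uniform(0, 2 * np.pi, size=4)
    factor = np.ones_like(theta)
    for k, a, phi in zip(range(2, 6), amps, phases):
        factor = factor + irregularity * a * np.cos(k * theta + phi)
    return factor


def _mass_mask(shape: tuple[int, int], center: tuple[float, float],
               radii: tuple[float, float], irregularity: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a star-perturbed ellipse.

    Returns the boolean mask and the normalized radial coordinate
    (0 at the center, 1 at the boundary) clipped to [0, 1].
    """
    rr, cc = np.indices(shape, dtype=float)
    dy = rr - center[0]
    dx = cc - center[1]
    rho = np.hypot(dy / radii[0], dx / radii[1])
    theta = np.arctan2(dy, dx)
    boundary = _star_radius(theta, irregularity, rng)
    mask = rho <= boundary
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_n = np.where(boundary > 0, rho / boundary, 1.0)
    return mask, np.clip(rho_n, 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Generate a mammogram-like phantom.

    Returns
    -------
    image : float array in [0, 1]
        ``(height, width)`` phantom; background outside the breast is 0.
    mass_masks : list of bool arrays
        One full-frame mask per planted mass, disjoint and fully inside
        the breast.
    pectoral_mask : bool array
        Support of the pectoral wedge (all-False when not requested).

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rr, cc = np.indices((h, w), dtype=float)

    # breast half-disc anchored to the left edge (chest wall)
    breast_center = (h / 2.0, 0.0)
    breast_radius = 0.94 * min(h / 2.0, float(w))
    dist = np.hypot(rr - breast_center[0], cc - breast_center[1])
    breast = dist <= breast_radius

    base = 0.38 - 0.08 * (dist / breast_radius)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=4.0, mode="reflect")
    texture /= max(texture.std(), 1e-12)
    img = base + 0.03 * texture

    pectoral = np.zeros((h, w), dtype=bool)
    if spec.with_pectoral:
        # top-corner triangle: col < c0 * (1 - row / r0)
        r0, c0 = 0.38 * h, 0.32 * w
        pectoral = (cc < c0 * (1.0 - rr / r0)) & (rr < r0) & breast
        img[pectoral] = 0.80 + 0.02 * texture[pectoral]

    # place disjoint masses fully inside the breast, away from the wedge
    lo, hi = spec.mass_radius_range
    masks: list[np.ndarray] = []
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.n_masses):
        ok = False
        for _attempt in range(300):
            r0 = rng.uniform(lo, hi)
            rmax = 1.35 * r0
            cy = rng.uniform(rmax + 2, h - rmax - 2)
            cx = rng.uniform(rmax + 6, w - rmax - 2)
            if np.hypot(cy - breast_center[0], cx - breast_center[1]) + rmax > breast_radius - 2:
                continue
            if spec.with_pectoral and cx < 0.32 * w * (1.0 - (cy - rmax) / (0.38 * h)) + rmax:
                continue
            if any(np.hypot(cy - py, cx - px) < rmax + pr + 4 for py, px, pr in placed):
                continue
            mask, rho_n = _mass_mask((h, w), (cy, cx), (r0, r0),
                                     spec.irregularity, rng)
            if mask.sum() < 1:
                continue
            img[mask] += spec.contrast * (0.65 + 0.35 * (1.0 - rho_n[mask] ** 2))
            masks.append(mask)
            placed.append((cy, cx, rmax))
            ok = True
            break
        if not ok:
            raise RuntimeError("could not place masses disjointly inside the breast")

    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal((h, w))

    img = np.where(breast, np.clip(img, 0.0, 1.0), 0.0)

    if spec.pectoral_side == "right":
        img = img[:, ::-1].copy()
        masks = [m[:, ::-1].copy() for m in masks]
        pectoral = pectoral[:, ::-1].copy()

    return img, masks, pectoral


def make_sparse_roi(size: tuple[int, int], irregularity: float = 0.3,
                    contrast: float = 0.4, seed: int = 0, *,
                    texture_amp: float = 0.04,
                    group: int | None = None) -> SparseROI:
    """Generate a single sparse ROI patch.

    Pixels outside the star-perturbed elliptical mass support are exactly
    zero; pixels inside are strictly positive, brightest at the center.

    Parameters
    ----------
    size
        ``(rows, cols)``; must be at least 25 x 22, the smallest candidate
        patch the descriptor stage accepts.
    irregularity
        Radial perturbation amplitude in [0, 1]; 0 gives an exact
        axis-aligned ellipse.
    contrast
        Peak in-mass intensity scale in [0, 1] units.
    """
    h, w = int(size[0]), int(size[1])
    if h < MIN_ROI_SHAPE[0] or w < MIN_ROI_SHAPE[1]:
        raise ValueError(
            f"ROI size must be at least {MIN_ROI_SHAPE[0]} x {MIN_ROI_SHAPE[1]}, got {h} x {w}")
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    rng = np.random.default_rng(seed)
    radii = (0.33 * h, 0.33 * w)
    mask, rho_n = _mass_mask((h, w), ((h - 1) / 2.0, (w - 1) / 2.0),
                             radii, irregularity, rng)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=1.5, mode="reflect")
    texture /= max(texture.std(), 1e-12)
    values = contrast * (0.55 + 0.45 * (1.0 - rho_n ** 2)) + texture_amp * texture
    pixels = np.where(mask, np.clip(values, 0.02, 1.0), 0.0)
    return SparseROI(pixels=pixels, group=group)


def make_labeled_roi_set(n_pos: int, n_neg: int, seed: int = 0, *,
                         pos_contrast: float = 0.4,
                         neg_contrast: float = 0.1,
                         size_range: tuple[tuple[int, int], tuple[int, int]] = ((25, 44), (22, 40)),
                         ) -> list[tuple[SparseROI, int]]:
    """Generate a labeled pool of sparse ROIs for classifier evaluation.

    Positives (label 1) are bright, smoothly-shaded irregular masses;
    negatives (label 0) reuse the same sparse support machinery but with
    low contrast and stronger internal texture, mimicking the false
    positives that survive pixel-count filtering.  Each ROI gets a unique
    group id (it stands for an independent source image).  The returned
    list is shuffled deterministically by ``seed``.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    (h_lo, h_hi), (w_lo, w_hi) = size_range
    out: list[tuple[SparseROI, int]] = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        size = (int(rng.integers(h_lo, h_hi + 1)), int(rng.integers(w_lo, w_hi + 1)))
        irr = float(rng.uniform(0.25, 0.5))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if label:
            roi = make_sparse_roi(size, irr, pos_contrast, sub_seed,
                                  texture_amp=0.04, group=i)
        else:
            roi = make_sparse_roi(size, irr, neg_contrast, sub_seed,
                                  texture_amp=0.08, group=i)
        out.append((roi, label))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img * 255), 0, 255).astype(np.uint8)


def write_phantom(directory: str, image: np.ndarray,
                  mass_masks: list[np.ndarray],
                  pectoral_mask: np.ndarray) -> None:
    """Write a phantom as PNG: image plus 0/255 masks."""
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    iio.imwrite(os.path.join(directory, "phantom.png"), _to_u8(image))
    for i, m in enumerate(mass_masks):
        iio.imwrite(os.path.join(directory, f"mass_{i:02d}.png"),
                    (m.astype(np.uint8) * 255))
    iio.imwrite(os.path.join(directory, "pectoral.png"),
                (pectoral_mask.astype(np.uint8) * 255))


def write_roi_set(directory: str, rois: list[SparseROI],
                  labels: list[int] | None = None) -> pd.DataFrame:
    """Write ROI patches as PNG plus a CSV manifest (filename, label, bbox)."""
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, roi in enumerate(rois):
        fname = f"roi_{i:04d}.png"
        iio.imwrite(os.path.join(directory, fname), _to_u8(roi.pixels))
        rows.append({
            "filename": fname,
            "label": labels[i] if labels is not None else -1,
            "bbox": "" if roi.bbox is None else ",".join(map(str, roi.bbox)),
            "group": -1 if roi.group is None else roi.group,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(directory, "manifest.csv"), index=False)
    return manifest
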