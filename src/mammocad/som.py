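"""Self-organizing-map segmentation and candidate extraction.

Every pixel is described by the 9 intensities of its 3 x 3 neighborhood
(center included, borders reflected).  A small SOM — by default a 2 x 2
grid of nodes, i.e. M = 4 clusters — is trained online: for each sampled
feature f the best-matching unit (BMU) c minimizes ||f - W_i||, and all
node weights move toward f under the Gaussian neighborhood kernel

    N_ci(t) = eta(t) * exp(-||m_c - m_i||^2 / (2 sigma^2(t))),

with the learning rate eta and kernel width sigma decaying exponentially
to 1% of their initial values over the training run.  After training,
each pixel is labeled by its BMU; the cluster with the highest mean image
intensity is taken as the mass cluster (masses are bright), and its
8-connected components whose pixel counts fall inside a pixel-level
threshold (PLT) band become region candidates.  Candidates are cropped to
tight bounding boxes with non-candidate pixels zeroed, yielding sparse
ROIs for the descriptor stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .roi import MIN_ROI_SHAPE, SparseROI, pad_to_min, validate_image

__all__ = [
    "extract_pixel_features",
    "SOMModel",
    "train_som",
    "assign_clusters",
    "PLTConfig",
    "RegionCandidate",
    "select_candidates",
    "extract_rois",
    "segment",
]

#: PLT band (pixel counts) for 1024 x 1024 small-format mammograms.
PLT_SMALL_FORMAT = (450, 31_500)


def extract_pixel_features(img: np.ndarray) -> np.ndarray:
    """3 x 3 neighborhood intensities for every pixel, borders reflected.

    Returns an ``(H*W, 9)`` array, rows in row-major pixel order; each row
    holds the window values row-major with the center at index 4.
    """
    img = validate_image(img)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3 x 3")
    padded = np.pad(img, 1, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3))
    return windows.reshape(img.shape[0] * img.shape[1], 9).copy()


def _node_grid(m: int) -> np.ndarray:
    """Near-square unit-spacing node coordinates; 2 x 2 for the default M=4."""
    rows = int(np.floor(np.sqrt(m)))
    while m % rows:
        rows -= 1
    cols = m // rows
    coords = [(r, c) for r in range(rows) for c in range(cols)]
    return np.asarray(coords, dtype=float)


@dataclass
class SOMModel:
    """A trained SOM: node weights plus the training configuration."""

    weights: np.ndarray          # (M, 9)
    grid: np.ndarray             # (M, 2) node coordinates m_i
    eta0: float
    sigma0: float
    iterations: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return self.weights.shape[0]


def train_som(features: np.ndarray, m: int = 4, iterations: int = 20_000,
              eta0: float = 0.5, sigma0: float = 1.0,
              seed: int = 0) -> SOMModel:
    """Train a SOM by online sampling of pixel features.

    ``eta(t) = eta0 * 0.01**(t/T)`` and likewise for ``sigma``; weights
    are initialized uniformly in [0, 1].  Deterministic for fixed seed.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != 9:
        raise ValueError("features must be (N, 9)")
    if m < 2:
        raise ValueError("need at least 2 clusters")
    if features.shape[0] < m:
        raise ValueError("need at least as many features as clusters")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(0.0, 1.0, size=(m, 9))
    grid = _node_grid(m)
    sq_grid_dist = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)  # (M, M)

    order = rng.integers(0, features.shape[0], size=iterations)
    t_frac = np.arange(iterations) / max(iterations, 1)
    etas = eta0 * 0.01 ** t_frac
    sigmas = sigma0 * 0.01 ** t_frac
    for t in range(iterations):
        f = features[order[t]]
        diff = f - weights
        c = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
        kernel = etas[t] * np.exp(-sq_grid_dist[c] / (2.0 * sigmas[t] ** 2))
        weights += kernel[:, None] * diff
    return SOMModel(weights=weights, grid=grid, eta0=eta0, sigma0=sigma0,
                    iterations=iterations, seed=seed)


def som_update(weights: np.ndarray, grid: np.ndarray, f: np.ndarray,
               eta: float, sigma: float) -> np.ndarray:
    """One BMU-and-neighborhood update step (exposed for testing)."""
    diff = f - weights
    c = int(np.argmin((diff ** 2).sum(1)))
    sq = ((grid - grid[c]) ** 2).sum(1)
    kernel = eta * np.exp(-sq / (2.0 * sigma ** 2))
    return weights + kernel[:, None] * diff


def assign_clusters(model: SOMModel, img: np.ndarray) -> np.ndarray:
    """Label every pixel by its best-matching unit (ties -> lowest index)."""
    feats = extract_pixel_features(img)
    d2 = ((feats[:, None, :] - model.weights[None, :, :]) ** 2).sum(-1)
    return np.argmin(d2, axis=1).reshape(img.shape)


@dataclass
class PLTConfig:
    """Pixel-level threshold: keep candidates with pixel counts in [min, max]."""

    min_pixels: int = PLT_SMALL_FORMAT[0]
    max_pixels: int = PLT_SMALL_FORMAT[1]

    def __post_init__(self) -> None:
        if not 0 < self.min_pixels < self.max_pixels:
            raise ValueError("require 0 < min_pixels < max_pixels")


@dataclass
class RegionCandidate:
    """A connected region from the cluster map.

    ``mask`` is cropped to the tight half-open bounding box
    ``(row0, col0, row1, col1)``; ``is_tp`` is an optional ground-truth
    slot filled during evaluation.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    pixel_count: int
    is_tp: bool | None = None

    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean() + self.bbox[0]), float(cc.mean() + self.bbox[1])


def select_candidates(cmap: np.ndarray, img: np.ndarray,
                      plt: PLTConfig) -> list[RegionCandidate]:
    """PLT-filtered 8-connected components of the brightest cluster.

    The cluster of interest is the label with the highest mean image
    intensity; its components with ``min_pixels <= count <= max_pixels``
    are returned (possibly none).
    """
    cmap = np.asarray(cmap)
    img = validate_image(img)
    if cmap.shape != img.shape:
        raise ValueError("cluster map and image shapes differ")
    labels = np.unique(cmap)
    means = [img[cmap == lab].mean() for lab in labels]
    bright = labels[int(np.argmax(means))]
    comp = measure.label(cmap == bright, connectivity=2)
    out: list[RegionCandidate] = []
    for region in measure.regionprops(comp):
        if plt.min_pixels <= region.area <= plt.max_pixels:
            r0, c0, r1, c1 = region.bbox
            out.append(RegionCandidate(mask=region.image.copy(),
                                       bbox=(r0, c0, r1, c1),
                                       pixel_count=int(region.area)))
    return out


def extract_rois(img: np.ndarray,
                 candidates: list[RegionCandidate]) -> list[SparseROI]:
    """Tight bounding-box crops with non-candidate pixels set exactly to 0.

    Crops smaller than 25 x 22 are zero-padded symmetrically to that
    minimum so every ROI is accepted by the descriptor stage.
    """
    img = validate_image(img)
    rois: list[SparseROI] = []
    for cand in candidates:
        r0, c0, r1, c1 = cand.bbox
        if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
            raise ValueError("candidate bounding box outside the image")
        patch = np.where(cand.mask, img[r0:r1, c0:c1], 0.0)
        rois.append(SparseROI(pixels=pad_to_min(patch), bbox=cand.bbox))
    return rois


def segment(img: np.ndarray, plt: PLTConfig | None = None, *, m: int = 4,
            iterations: int = 20_000, seed: int = 0,
            ) -> tuple[np.ndarray, list[RegionCandidate], list[SparseROI]]:
    """Convenience wrapper: features -> SOM -> candidates -> sparse ROIs."""
    plt = plt or PLTConfig()
    feats = extract_pixel_features(img)
    model = train_som(feats, m=m, iterations=iterations, seed=seed)
    cmap = assign_clusters(model, img)
    cands = select_candidates(cmap, img, plt)
    return cmap, cands, extract_rois(img, cands)
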