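"""Context-aware saliency maps from LAB patch dissimilarity.

The image is tiled into n x n pixel blocks described by their mean LAB color
and normalized center position.  Two blocks differ by

    D(p_i, p_j) = d_color(p_i, p_j) / (1 + c * d_position(p_i, p_j)),

both distances Euclidean: a block is conspicuous when it differs in color
from blocks that are *near* it.  The single-scale saliency of block i
averages its dissimilarity to its K most similar reference blocks,

    S_i = 1 - exp(-(1/K) * sum_k D(p_i, q_k)),

so S is always in [0, 1) and a block that resembles its best matches scores
near 0.  Maps computed at several image scales are averaged, and a context
correction attenuates saliency with the distance to the nearest attended
(above-threshold) pixel:  S_hat = S_bar * (1 - d_foci), with d_foci the
Euclidean distance to the attended set normalized by the image diagonal.
The correction can only lower saliency, never raise it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.color import rgb2lab
from skimage.transform import rescale, resize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SaliencyConfig:
    """Parameters of the context-aware saliency model.

    ``c`` weights position against color in the dissimilarity (default 3);
    ``K`` is the reference-set size (default 64 blocks); ``patch_size`` the
    block side in pixels; ``scales`` the relative image scales averaged over;
    ``threshold`` the attended-pixel cutoff for the context correction.
    ``neighbor_mode`` selects how the K reference blocks are chosen:
    ``"similar"`` (the K most similar blocks anywhere, the default) or
    ``"spatial"`` (the K spatially nearest blocks).
    """

    c: float = 3.0
    K: int = 64
    patch_size: int = 8
    scales: tuple = (1.0, 0.5, 0.25)
    threshold: float = 0.8
    neighbor_mode: str = "similar"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if len(self.scales) < 1:
            raise ValueError("at least one scale is required")
        if self.neighbor_mode not in ("similar", "spatial"):
            raise ValueError("neighbor_mode must be 'similar' or 'spatial'")


@dataclass(frozen=True)
class PatchGrid:
    """Mean-LAB block descriptors with normalized center positions."""

    descriptors: np.ndarray  # (n_patches, 3) mean LAB
    positions: np.ndarray  # (n_patches, 2) centers in [0, 1]^2
    grid_shape: tuple  # (rows, cols) of blocks
    scale: float = 1.0


@dataclass(frozen=True)
class SaliencyMap:
    """Per-pixel saliency in [0, 1] plus the attended set used, if any."""

    values: np.ndarray
    threshold: float | None = None
    attended: np.ndarray | None = field(default=None)


def block_dissimilarity(
    color_i: np.ndarray,
    position_i: np.ndarray,
    color_j: np.ndarray,
    position_j: np.ndarray,
    c: float,
) -> float:
    """Dissimilarity of two blocks: d_color / (1 + c * d_position)."""
    d_color = float(np.linalg.norm(np.subtract(color_i, color_j)))
    d_pos = float(np.linalg.norm(np.subtract(position_i, position_j)))
    return d_color / (1.0 + c * d_pos)


def make_patch_grid(
    image: np.ndarray, patch_size: int = 8, scale: float = 1.0
) -> PatchGrid:
    """Tile an RGB image into blocks of mean-LAB descriptors.

    Trailing rows/columns that do not fill a block are dropped; positions are
    block centers normalized by the image extent.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB, got {img.shape}")
    h, w = img.shape[:2]
    rows, cols = h // patch_size, w // patch_size
    if rows < 1 or cols < 1:
        raise ValueError(
            f"image {img.shape} smaller than one {patch_size}px block"
        )
    lab = rgb2lab(img[: rows * patch_size, : cols * patch_size])
    blocks = lab.reshape(rows, patch_size, cols, patch_size, 3)
    descriptors = blocks.mean(axis=(1, 3)).reshape(-1, 3)
    yc = (np.arange(rows) + 0.5) * patch_size / h
    xc = (np.arange(cols) + 0.5) * patch_size / w
    positions = np.stack(np.meshgrid(yc, xc, indexing="ij"), axis=-1)
    return PatchGrid(
        descriptors=descriptors,
        positions=positions.reshape(-1, 2),
        grid_shape=(rows, cols),
        scale=scale,
    )


def _dissimilarity_matrix(grid: PatchGrid, c: float) -> np.ndarray:
    d_color = cdist(grid.descriptors, grid.descriptors)
    d_pos = cdist(grid.positions, grid.positions)
    return d_color / (1.0 + c * d_pos)


def single_scale_saliency(grid: PatchGrid, cfg: SaliencyConfig) -> np.ndarray:
    """Per-block saliency S = 1 - exp(-mean D over the K reference blocks).

    Returns the block saliency as a (rows, cols) array.  With fewer than K
    other blocks available, all of them are used and the mean divides by the
    actual count.
    """
    n = len(grid.descriptors)
    if n == 0:
        raise ValueError("empty patch grid")
    if n == 1:
        return np.zeros((1, 1))
    d = _dissimilarity_matrix(grid, cfg.c)
    k = min(cfg.K, n - 1)
    if cfg.neighbor_mode == "spatial":
        order = np.argsort(cdist(grid.positions, grid.positions), axis=1)
        ref = np.take_along_axis(d, order[:, 1 : k + 1], axis=1)
        mean_d = ref.mean(axis=1)
    else:
        np.fill_diagonal(d, np.inf)  # a block is not its own reference
        smallest = np.partition(d, k - 1, axis=1)[:, :k]
        mean_d = smallest.mean(axis=1)
    return (1.0 - np.exp(-mean_d)).reshape(grid.grid_shape)


def _block_map_to_pixels(block_map: np.ndarray, shape: tuple) -> np.ndarray:
    return resize(
        block_map, shape, order=1, mode="edge", anti_aliasing=False
    )


def context_correction(
    mean_map: np.ndarray, threshold: float
) -> SaliencyMap:
    """Attenuate saliency by the distance to the nearest attended pixel.

    Attended pixels are those with saliency >= ``threshold``; if none
    qualifies the global maximum is attended (logged).  ``d_foci`` is the
    Euclidean distance to the attended set, normalized by the image
    diagonal, and the corrected map is ``mean_map * (1 - d_foci)``.
    """
    attended = mean_map >= threshold
    if not attended.any():
        logger.info(
            "no pixel reaches the saliency threshold %.3g; "
            "falling back to the global maximum", threshold,
        )
        attended = np.zeros_like(attended)
        attended[np.unravel_index(np.argmax(mean_map), mean_map.shape)] = True
    d = ndimage.distance_transform_edt(~attended)
    diagonal = float(np.hypot(*mean_map.shape))
    d_foci = np.clip(d / diagonal, 0.0, 1.0)
    return SaliencyMap(
        values=mean_map * (1.0 - d_foci), threshold=threshold,
        attended=attended,
    )


def context_aware_saliency(
    image: np.ndarray, cfg: SaliencyConfig | None = None
) -> SaliencyMap:
    """Full pipeline: per-scale block saliency, averaged, context-corrected."""
    cfg = cfg or SaliencyConfig()
    img = np.asarray(image, dtype=float)
    shape = img.shape[:2]
    per_scale = []
    for scale in cfg.scales:
        scaled = (
            img
            if scale == 1.0
            else rescale(img, scale, channel_axis=2, anti_aliasing=True)
        )
        grid = make_patch_grid(scaled, cfg.patch_size, scale)
        per_scale.append(
            _block_map_to_pixels(single_scale_saliency(grid, cfg), shape)
        )
    mean_map = np.clip(np.mean(per_scale, axis=0), 0.0, 1.0)
    return context_correction(mean_map, cfg.threshold)
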