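"""PET/MRI image fusion: IHS color transform + shift-invariant multiscale merge.

The fusion stage combines a functional PET plane with a co-registered
anatomical MRI plane.  The color image is moved into an
intensity-hue-saturation (IHS) space via a fixed linear transform (intensity
is the channel mean; the two chroma axes are orthogonal to the gray
diagonal, so hue/saturation follow as polar coordinates).  Each plane is
split into one low-frequency band and L high-frequency detail bands with an
a-trous (stationary) wavelet pyramid — a shift-invariant decomposition with
perfect reconstruction at any image size.  The fused plane takes its low
band from the PET (the functional signal) and each detail band by the
max-absolute-coefficient rule (the anatomical edges), then reconstructs and
clips to [0, 1].

Inputs are assumed co-registered; registration is out of scope (the phantom
generator emits co-registered planes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# chroma rows orthogonal to (1,1,1): gray pixels have zero saturation
_IHS = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [1 / np.sqrt(6), 1 / np.sqrt(6), -2 / np.sqrt(6)],
        [1 / np.sqrt(2), -1 / np.sqrt(2), 0.0],
    ]
)
_IHS_INV = np.linalg.inv(_IHS)

# B3-spline scaling kernel of the starlet transform
_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class GihsImage:
    """Intensity/hue/saturation planes of an RGB image."""

    intensity: np.ndarray
    hue: np.ndarray
    saturation: np.ndarray


@dataclass(frozen=True)
class MultiscaleStack:
    """One low-frequency band plus L detail bands, all at source size."""

    low: np.ndarray
    highs: tuple

    @property
    def levels(self) -> int:
        return len(self.highs)


def rgb_to_gihs(image: np.ndarray) -> GihsImage:
    """Forward IHS transform of an RGB image with values in [0, 1]."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got {img.shape}")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("RGB values must lie in [0, 1]")
    i, v1, v2 = np.einsum("ij,hwj->ihw", _IHS, img)
    return GihsImage(
        intensity=i,
        hue=np.arctan2(v2, v1),
        saturation=np.hypot(v1, v2),
    )


def gihs_to_rgb(gihs: GihsImage) -> np.ndarray:
    """Inverse IHS transform; round-trips the forward transform to 1e-6."""
    v1 = gihs.saturation * np.cos(gihs.hue)
    v2 = gihs.saturation * np.sin(gihs.hue)
    ivv = np.stack([gihs.intensity, v1, v2], axis=-1)
    return np.einsum("ij,hwj->hwi", _IHS_INV, ivv)


def _atrous_smooth(plane: np.ndarray, level: int) -> np.ndarray:
    """Separable B3-spline smoothing with 2**level holes, mirror boundary."""
    kernel = np.zeros(4 * 2**level + 1)
    kernel[:: 2**level] = _B3
    out = ndimage.correlate1d(plane, kernel, axis=0, mode="mirror")
    return ndimage.correlate1d(out, kernel, axis=1, mode="mirror")


def multiscale_decompose(plane: np.ndarray, levels: int) -> MultiscaleStack:
    """Split a 2D plane into 1 low + ``levels`` high bands (starlet pyramid).

    All bands have the source shape (no subsampling, hence shift
    invariance), and ``low + sum(highs)`` reconstructs the source exactly.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2D plane, got shape {plane.shape}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if 2**levels > min(plane.shape):
        raise ValueError(
            f"{levels} levels too deep for a {plane.shape} plane"
        )
    current = plane
    highs = []
    for level in range(levels):
        smooth = _atrous_smooth(current, level)
        highs.append(current - smooth)
        current = smooth
    return MultiscaleStack(low=current, highs=tuple(highs))


def multiscale_reconstruct(stack: MultiscaleStack) -> np.ndarray:
    """Invert :func:`multiscale_decompose` (a plain sum of bands)."""
    return stack.low + np.sum(stack.highs, axis=0)


def fuse_pet_mri(
    mri_plane: np.ndarray, pet_plane: np.ndarray, *, levels: int = 3
) -> np.ndarray:
    """Fuse a PET plane (function) with an MRI plane (anatomy detail).

    Low band from PET, detail bands by max absolute coefficient, output
    clipped to [0, 1].
    """
    mri = np.asarray(mri_plane, dtype=float)
    pet = np.asarray(pet_plane, dtype=float)
    if mri.shape != pet.shape:
        raise ValueError(f"shape mismatch: MRI {mri.shape}, PET {pet.shape}")
    mri_stack = multiscale_decompose(mri, levels)
    pet_stack = multiscale_decompose(pet, levels)
    fused_highs = tuple(
        np.where(np.abs(m) >= np.abs(p), m, p)
        for m, p in zip(mri_stack.highs, pet_stack.highs)
    )
    fused = multiscale_reconstruct(
        MultiscaleStack(low=pet_stack.low, highs=fused_highs)
    )
    return np.clip(fused, 0.0, 1.0)
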