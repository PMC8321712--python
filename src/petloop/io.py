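"""File-format helpers: NIfTI volumes, PNG scenes/masks, CSV tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .phantom import DynamicVolume, RoiLabelMap
from .tac import TIME_GRID


def save_dynamic_volume(volume: DynamicVolume, path) -> None:
    """Write a 4D dynamic volume as NIfTI; frame spacing goes in the header."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    step = float(volume.times[1] - volume.times[0])
    img.header.set_zooms(volume.spacing + (step * 60.0,))  # frame step in sec
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_dynamic_volume(path) -> DynamicVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D volume")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicVolume(data=data, times=TIME_GRID.copy(), spacing=spacing)


def save_label_map(labels: RoiLabelMap, path, *, spacing=(2.0, 2.0, 2.0)) -> None:
    img = nib.Nifti1Image(
        labels.data.astype(np.int16), np.diag(list(spacing) + [1.0])
    )
    nib.save(img, str(path))


def load_label_map(path, names: dict) -> RoiLabelMap:
    data = np.asarray(nib.load(str(path)).dataobj).astype(np.int16)
    return RoiLabelMap(data=data, names=dict(names))


def save_image(image: np.ndarray, path) -> None:
    """Write a float image in [0,1] (grayscale or RGB) as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(str(path), np.round(arr * 255).astype(np.uint8))


def load_image(path) -> np.ndarray:
    """Read a PNG as float in [0,1]; RGBA is truncated to RGB."""
    arr = np.asarray(iio.imread(str(path)), dtype=float) / 255.0
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr


def save_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(str(path))) > 127


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
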