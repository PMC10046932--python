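"""Image I/O: PNG/TIFF (8- or 16-bit) and NIfTI, normalized to [0, 1].

Integer rasters are scaled by their dtype maximum on read and re-quantized
on write; NIfTI volumes are stored as float and round-trip exactly.  3D
NIfTI volumes can be iterated slice by slice.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

_RASTER_EXT = {".png", ".tif", ".tiff"}


def _is_nifti(path: Path) -> bool:
    return path.suffix == ".nii" or path.name.endswith(".nii.gz")


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2D grayscale image as float64 in [0, 1].

    RGB rasters are converted by luminance weighting; unsupported formats
    raise a ValueError naming the extension.
    """
    path = Path(path)
    if _is_nifti(path):
        data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        if data.ndim != 2:
            raise ValueError("use read_volume for 3D NIfTI files")
        return np.clip(data, 0.0, 1.0)
    if path.suffix.lower() not in _RASTER_EXT:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 3:
        from .preprocessing import to_grayscale

        arr = to_grayscale(arr[:, :, :3])
    return arr


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image; 8-bit for PNG/TIFF, float for NIfTI."""
    path = Path(path)
    img = np.asarray(img, dtype=np.float64)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(img.astype(np.float64), affine=np.eye(4)),
                 str(path))
        return
    if path.suffix.lower() not in _RASTER_EXT:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    iio.imwrite(path, np.round(np.clip(img, 0, 1) * 255).astype(np.uint8))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_volume(path: str | Path) -> np.ndarray:
    """Read a 3D NIfTI volume as float64 (H, W, n_slices)."""
    data = np.asarray(nib.load(str(Path(path))).dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return data


def iter_slices(path: str | Path):
    """Yield 2D slices of a 3D NIfTI volume, clipped to [0, 1]."""
    vol = read_volume(path)
    for k in range(vol.shape[2]):
        yield np.clip(vol[:, :, k], 0.0, 1.0)
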