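"""NIfTI / raster IO helpers around the core data structures."""

from __future__ import annotations

import os

import numpy as np
import nibabel as nib

from .fitting import FractionMaps

__all__ = [
    "load_dwi",
    "load_mask",
    "save_volume",
    "save_fraction_maps",
    "load_raster_mask",
]


def load_dwi(path):
    """Load a 4D diffusion-weighted NIfTI; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    return data, img.affine


def load_mask(path, shape=None):
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match {shape}")
    return mask


def save_volume(data, affine, path):
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def save_fraction_maps(maps: FractionMaps, outdir, prefix: str = "dbsi"):
    """One float32 NIfTI per fraction channel, plus the fitted-voxel mask."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, arr in maps.maps.items():
        p = os.path.join(outdir, f"{prefix}_{name}_fraction.nii.gz")
        save_volume(arr, maps.affine, p)
        paths[name] = p
    p = os.path.join(outdir, f"{prefix}_mask.nii.gz")
    save_volume(maps.mask.astype(np.uint8), maps.affine, p)
    paths["mask"] = p
    return paths


def load_raster_mask(path):
    """Binary stain mask from TIFF/PNG (0/255 or 0/1, any channel layout)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)
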