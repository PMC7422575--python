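"""Image import/export: portable ``.npy`` arrays and NIfTI volumes.

NIfTI volumes are treated slice-wise along the last axis; real-valued
volumes become complex images with zero imaginary part.  All images are
returned unit-normalized unless ``normalize=False``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .fourier import ComplexImage
from .phantom import normalize as _normalize

__all__ = ["load_image", "load_nifti_slices", "save_image", "save_nifti"]


def load_image(path: str | Path, normalize: bool = True) -> ComplexImage:
    """Load one 2-D complex image from a ``.npy`` file."""
    img = ComplexImage(np.load(Path(path)))
    return _normalize(img) if normalize else img


def save_image(img: ComplexImage, path: str | Path) -> None:
    np.save(Path(path), img.data)


def load_nifti_slices(path: str | Path, normalize: bool = True) -> list[ComplexImage]:
    """Load a NIfTI volume as a list of axial complex slices."""
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim == 2:
        vol = vol[..., None]
    if vol.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D NIfTI volume, got shape {vol.shape}")
    out = []
    for k in range(vol.shape[-1]):
        img = ComplexImage(vol[..., k].astype(np.complex128))
        out.append(_normalize(img) if normalize else img)
    return out


def save_nifti(images: list[ComplexImage], path: str | Path,
               magnitude_only: bool = True) -> None:
    """Stack slices into a NIfTI volume (magnitude by default, since
    NIfTI viewers expect real data; complex data round-trips via .npy)."""
    stack = np.stack([img.data for img in images], axis=-1)
    data = np.abs(stack) if magnitude_only else stack.real
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4)), str(path))
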