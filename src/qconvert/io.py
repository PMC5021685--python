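"""NIfTI-1 I/O for diffusion-weighted datasets, masks and gradient-deviation fields."""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .schemes import BTable, GradientDeviationField, load_btable

__all__ = ["DWIData", "read_dwi", "save_nifti"]


@dataclass
class DWIData:
    """A loaded 4D diffusion dataset with its b-table and optional fields."""

    data: np.ndarray  # (X, Y, Z, n_volumes)
    btable: BTable
    affine: np.ndarray
    mask: np.ndarray | None = None
    grad_dev: GradientDeviationField | None = None

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:-1]


def read_dwi(
    nifti_path,
    bval_path,
    bvec_path=None,
    mask_path=None,
    grad_dev_path=None,
) -> DWIData:
    """Load a 4D DWI NIfTI with its b-table and optional mask/grad_dev.

    The b-table may be FSL bval/bvec (two paths) or 4-column text (one
    path).  The NIfTI 4th dimension must match the b-table length; masks
    and the 9-component grad_dev volume must share the spatial grid.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4D volume, got {data.ndim}D")
    btable = load_btable(bval_path, bvec_path)
    if data.shape[-1] != btable.n_volumes:
        raise ValueError(
            f"{nifti_path} has {data.shape[-1]} volumes but the b-table "
            f"has {btable.n_volumes}"
        )
    mask = None
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.get_fdata()) > 0
        if mask.shape != data.shape[:-1]:
            raise ValueError("mask grid does not match the DWI grid")
    grad_dev = None
    if grad_dev_path is not None:
        gd_img = nib.load(str(grad_dev_path))
        gd = np.asarray(gd_img.get_fdata(), dtype=float)
        if gd.ndim != 4 or gd.shape[-1] != 9:
            raise ValueError("grad_dev must be a 9-component 4D volume")
        if gd.shape[:-1] != data.shape[:-1]:
            raise ValueError("grad_dev grid does not match the DWI grid")
        grad_dev = GradientDeviationField.from_flat(gd)
    return DWIData(data, btable, np.asarray(img.affine), mask, grad_dev)


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write an array as NIfTI-1 (float32 on disk)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))
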