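"""File I/O: NIfTI / NRRD rasters and CSV metric tables.

Only axis-aligned geometry is supported (no oblique orientation matrices):
NIfTI affines must be diagonal with positive spacing, NRRD direction
matrices must be the identity scaled by spacing.  Masks are written as
uint8 0/1, doses as float64 Gy.
"""

from __future__ import annotations

import os
from importlib import resources

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import FormatError
from .grid import DoseGrid, Mask, VoxelGrid

__all__ = [
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "read_table",
    "write_table",
    "load_table1",
    "TABLE_COLUMNS",
]

#: Column schema of per-case plan-metric tables.
TABLE_COLUMNS = [
    "case_id",
    "lrtv_cc",
    "vortex_cc",
    "valley_cc",
    "vortex_ratio_pct",
    "vortex_dose_gy",
    "valley_dose_gy",
    "vpdr_pct",
    "peripheral_dose_gy",
]


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _is_nrrd(path: str) -> bool:
    return path.endswith(".nrrd")


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _read_raster(path: str) -> tuple[np.ndarray, VoxelGrid]:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        img = nib.load(path)
        affine = np.asarray(img.affine, dtype=float)
        rot = affine[:3, :3]
        if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6):
            raise FormatError(f"{path}: only axis-aligned (diagonal affine) grids are supported")
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise FormatError(f"{path}: spacings must be positive, got {spacing}")
        origin = affine[:3, 3]
        values = np.asarray(img.dataobj)
    elif _is_nrrd(path):
        img = sitk.ReadImage(path)
        direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise FormatError(f"{path}: only identity-direction NRRD grids are supported")
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = np.asarray(img.GetOrigin(), dtype=float)
        # SimpleITK arrays come back (z, y, x); package order is (x, y, z)
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    else:
        raise FormatError(f"unsupported raster format: {path} (use .nii/.nii.gz/.nrrd)")
    if values.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={values.ndim}")
    grid = VoxelGrid(tuple(values.shape), tuple(spacing), tuple(origin))
    return values, grid


def _write_raster(path: str, values: np.ndarray, grid: VoxelGrid) -> None:
    if _is_nifti(path):
        affine = np.diag(list(grid.spacing) + [1.0])
        affine[:3, 3] = grid.origin
        nib.save(nib.Nifti1Image(values, affine), path)
    elif _is_nrrd(path):
        img = sitk.GetImageFromArray(values.transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in grid.spacing))
        img.SetOrigin(tuple(float(o) for o in grid.origin))
        sitk.WriteImage(img, path)
    else:
        raise FormatError(f"unsupported raster format: {path} (use .nii/.nii.gz/.nrrd)")


def read_mask(path: str) -> Mask:
    """Read a binary mask (any integer type with values 0/1)."""
    values, grid = _read_raster(path)
    if not np.all(np.isfinite(values.astype(float))):
        raise FormatError(f"{path}: mask contains non-finite values")
    uniq = np.unique(values)
    if not np.all(np.isin(uniq, (0, 1))):
        raise FormatError(f"{path}: mask values must be 0/1, found {uniq[:10]}")
    return Mask(grid, values.astype(bool))


def write_mask(path: str, mask: Mask) -> None:
    _write_raster(path, mask.values.astype(np.uint8), mask.grid)


def read_dose(path: str) -> DoseGrid:
    """Read a dose grid in Gy; NaN or negative voxels are rejected."""
    values, grid = _read_raster(path)
    values = values.astype(np.float64)
    if np.any(~np.isfinite(values)):
        raise FormatError(f"{path}: dose contains NaN/inf voxels")
    if np.any(values < 0):
        raise FormatError(f"{path}: dose contains negative voxels")
    return DoseGrid(grid, values)


def write_dose(path: str, dose: DoseGrid) -> None:
    _write_raster(path, np.asarray(dose.values, dtype=np.float64), dose.grid)


# ---------------------------------------------------------------------------
# metric tables
# ---------------------------------------------------------------------------

def read_table(path: str) -> pd.DataFrame:
    """Read a per-case plan-metric CSV; the header must match TABLE_COLUMNS."""
    df = pd.read_csv(path)
    if list(df.columns) != TABLE_COLUMNS:
        raise FormatError(
            f"{path}: column header {list(df.columns)} does not match {TABLE_COLUMNS}"
        )
    return df


def write_table(path: str, table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"table is missing columns {missing}")
    table.loc[:, TABLE_COLUMNS].to_csv(path, index=False)


def load_table1() -> pd.DataFrame:
    """The packaged 22-case reference cohort (printed per-case plan metrics,
    stored verbatim — including the source table's internal rounding
    inconsistencies; it is never regenerated)."""
    with resources.as_file(
        resources.files("latticeforge").joinpath("data/table1.csv")
    ) as p:
        return read_table(str(p))
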