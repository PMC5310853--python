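"""Reading and writing 3D volumes with physical geometry.

Supported formats and their native-to-internal axis mapping:

============  =====================  ==========================================
format        native array order     mapping to internal (x, y, z)
============  =====================  ==========================================
NIfTI         (i, j, k)              identity; spacing = pixdim[1:4]
DICOM series  per-slice (row, col)   col -> x, row -> y, slice -> z
TIFF stack    (page, row, col)       col -> x, row -> y, page -> z
MetaImage     sitk array (z, y, x)   transposed; spacing already (x, y, z)
============  =====================  ==========================================

Unit handling: NIfTI persists the unit tag (xyzt_units micron/mm) and round
trips it. MetaImage and TIFF carry no length unit on disk, so callers pass
``unit=`` on read (default "mm"); TIFF additionally requires ``spacing=``
and reading a TIFF without it raises :class:`MissingMetadataError` rather
than silently assuming 1.0. DICOM is read-only, always in mm, with rescale
slope/intercept applied so clinical values are in HU.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .errors import FormatError, MissingMetadataError
from .grid import VoxelGrid

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mhd", ".mha")
_TIFF_SUFFIXES = (".tif", ".tiff")

_WRITE_FORMATS = "NIfTI (.nii/.nii.gz), MetaImage (.mhd/.mha), TIFF (.tif/.tiff)"


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path, format: str | None = None, spacing=None, unit: str | None = None) -> VoxelGrid:
    """Read a 3D volume into a :class:`VoxelGrid`.

    Parameters
    ----------
    path : str or Path
        File, or directory containing a DICOM series.
    format : {"nifti", "dicom", "tiff", "meta"}, optional
        Explicit format hint; inferred from the path otherwise.
    spacing : (sx, sy, sz), optional
        Required for TIFF stacks (which store no calibrated 3D spacing);
        overrides file metadata elsewhere.
    unit : {"um", "mm"}, optional
        Length unit for formats that do not persist one (TIFF, MetaImage;
        default "mm"). Ignored for NIfTI when the file declares a unit.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path, unit)
    if fmt == "dicom":
        return _read_dicom_series(path)
    if fmt == "tiff":
        return _read_tiff(path, spacing, unit or "mm")
    if fmt == "meta":
        return _read_meta(path, unit or "mm")
    raise FormatError(f"unrecognized volume format for {path}")


def write_volume(grid: VoxelGrid, path) -> None:
    """Write `grid` so that :func:`read_volume` recovers identical data,
    spacing and origin. Unsupported extensions raise :class:`FormatError`.
    """
    path = Path(path)
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        _write_nifti(grid, path)
    elif suffix in _META_SUFFIXES:
        _write_meta(grid, path)
    elif suffix in _TIFF_SUFFIXES:
        _write_tiff(grid, path)
    else:
        raise FormatError(
            f"unsupported output extension {suffix!r}; supported: {_WRITE_FORMATS}"
        )


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom"
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        return "nifti"
    if suffix in _TIFF_SUFFIXES:
        return "tiff"
    if suffix in _META_SUFFIXES:
        return "meta"
    if suffix == ".dcm":
        return "dicom"
    raise FormatError(f"cannot infer format of {path}; pass format= explicitly")


# -- NIfTI ------------------------------------------------------------------

_NIFTI_UNIT_IN = {"micron": "um", "mm": "mm"}
_NIFTI_UNIT_OUT = {"um": "micron", "mm": "mm"}


def _read_nifti(path: Path, unit: str | None) -> VoxelGrid:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    file_unit = _NIFTI_UNIT_IN.get(img.header.get_xyzt_units()[0])
    origin = img.affine[:3, 3]
    return VoxelGrid(
        data=data,
        spacing=tuple(float(z) for z in zooms),
        origin=tuple(float(o) for o in origin),
        unit=file_unit or unit or "mm",
    )


def _write_nifti(grid: VoxelGrid, path: Path) -> None:
    import nibabel as nib

    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asanyarray(grid.data), affine)
    img.header.set_zooms(grid.spacing)
    img.header.set_xyzt_units(_NIFTI_UNIT_OUT[grid.unit])
    nib.save(img, str(path))


# -- DICOM series -----------------------------------------------------------


def _read_dicom_series(path: Path) -> VoxelGrid:
    import pydicom

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
    else:
        files = [path]
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files (DICOMDIR, reports)
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM images with pixel data found under {path}")

    def _zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=_zpos)
    first = slices[0]
    try:
        row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    except Exception as exc:
        raise MissingMetadataError(f"DICOM series lacks PixelSpacing: {exc}") from exc
    if len(slices) > 1 and hasattr(first, "ImagePositionPatient"):
        zs = np.array([_zpos(s) for s in slices])
        z_sp = float(np.mean(np.diff(zs)))
    else:
        z_sp = float(getattr(first, "SliceThickness", 0) or 0)
    if z_sp <= 0:
        raise MissingMetadataError("cannot determine DICOM slice spacing")

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    vol = np.stack(planes, axis=0)  # (z, row=y, col=x)
    data = np.transpose(vol, (2, 1, 0))  # -> (x, y, z)
    if hasattr(first, "ImagePositionPatient"):
        ipp = first.ImagePositionPatient
        origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    else:
        origin = (0.0, 0.0, 0.0)
    return VoxelGrid(data=data, spacing=(col_sp, row_sp, z_sp), origin=origin, unit="mm")


# -- TIFF stack -------------------------------------------------------------


def _read_tiff(path: Path, spacing, unit: str) -> VoxelGrid:
    import tifffile

    if spacing is None:
        raise MissingMetadataError(
            f"TIFF stacks carry no calibrated 3D voxel spacing; pass spacing=(sx, sy, sz) "
            f"to read {path} (spacing is never silently assumed to be 1.0)"
        )
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable TIFF file {path}: {exc}") from exc
    if arr.ndim != 3:
        raise FormatError(f"expected a multi-page TIFF stack, got shape {arr.shape}")
    data = np.transpose(arr, (2, 1, 0))  # (page=z, row=y, col=x) -> (x, y, z)
    return VoxelGrid(data=data, spacing=tuple(float(s) for s in spacing), unit=unit)


def _write_tiff(grid: VoxelGrid, path: Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.transpose(np.asarray(grid.data), (2, 1, 0)))


# -- MetaImage --------------------------------------------------------------


def _read_meta(path: Path, unit: str) -> VoxelGrid:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable MetaImage file {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D MetaImage volume, got shape {arr.shape}")
    return VoxelGrid(
        data=np.transpose(arr, (2, 1, 0)),
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
        unit=unit,
    )


def _write_meta(grid: VoxelGrid, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.transpose(np.asarray(grid.data), (2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))
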