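"""Reading and writing CT volumes.

The working representation is :class:`CTVolume`: a 3-D scalar field in
Hounsfield units (HU) together with the voxel->world affine.  Everything
downstream (cropping, registration, region densities) assumes the canonical
right-anterior-superior (RAS) orientation, so both readers reorient on load.
Scanner padding values below -1024 HU (air) are mapped to the -1024 sentinel
so that all loaded intensities are finite, calibrated HU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

from .errors import (
    CalibrationError,
    DimensionalityError,
    FormatError,
    ParameterError,
    SeriesError,
)

HU_AIR = -1024.0
_DET_TOL = 1e-12


def _canonicalize(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reorder/flip axes so the array is in RAS voxel order."""
    ornt = nib.orientations.io_orientation(affine)
    data2 = nib.orientations.apply_orientation(data, ornt)
    affine2 = affine @ nib.orientations.inv_ornt_aff(ornt, data.shape)
    return np.ascontiguousarray(data2), affine2


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class CTVolume:
    """A 3-D CT image in Hounsfield units.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in HU; always finite.
    affine : ndarray, shape (4, 4)
        Maps 0-based voxel index (i, j, k, 1) to the world coordinate (mm) of
        that voxel's center.
    spacing : ndarray, shape (3,)
        Per-axis voxel size in mm (column norms of the affine).
    orientation_code : tuple of str
        Axis labels, e.g. ``('R', 'A', 'S')``.
    """

    data: np.ndarray
    affine: np.ndarray
    spacing: np.ndarray = field(init=False)
    orientation_code: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"CTVolume requires a 3-D array, got shape {self.data.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ParameterError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < _DET_TOL:
            raise ParameterError("affine must be invertible")
        self.spacing = _spacing_from_affine(self.affine)
        if np.any(self.spacing <= 0):
            raise ParameterError("voxel spacing must be strictly positive")
        self.orientation_code = tuple(nib.aff2axcodes(self.affine))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel = |det| of the 3x3 block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """World mm coordinates of voxel indices ``ijk`` (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def with_data(self, data: np.ndarray) -> "CTVolume":
        """Same grid, new intensities."""
        return CTVolume(data=data, affine=self.affine.copy())


@dataclass
class LabelVolume:
    """Integer region codes on a reference grid.

    ``code_map`` maps each nonzero code to ``{"name": ..., "hemisphere": ...}``;
    hemisphere is ``"left"``, ``"right"`` or ``None``.  Code 0 is background.
    """

    labels: np.ndarray
    affine: np.ndarray
    code_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(
                f"LabelVolume requires a 3-D array, got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(np.int32)
            if not np.allclose(lab, self.labels):
                raise ParameterError("labels must be integer-valued")
            self.labels = lab
        if self.labels.min() < 0:
            raise ParameterError("label codes must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def as_bool(self) -> np.ndarray:
        return self.labels > 0


def _as_bool_mask(mask) -> np.ndarray:
    """Accept a LabelVolume or an array; return a boolean array."""
    if isinstance(mask, LabelVolume):
        return mask.as_bool()
    return np.asarray(mask) > 0


def read_nifti(path) -> CTVolume:
    """Load a single 3-D NIfTI volume as a canonically oriented :class:`CTVolume`.

    Raises
    ------
    FormatError
        If the file is missing or not a readable NIfTI image.
    DimensionalityError
        For 4-D (or higher) images, naming the offending shape.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    shape = img.shape
    if len(shape) != 3:
        raise DimensionalityError(
            f"expected a 3-D volume, got shape {tuple(shape)} in {path}"
        )
    data = np.asarray(img.get_fdata(dtype=np.float32))
    data[~np.isfinite(data)] = HU_AIR
    np.maximum(data, HU_AIR, out=data)
    data, affine = _canonicalize(data, img.affine)
    return CTVolume(data=data, affine=affine)


def write_nifti(vol, path) -> None:
    """Write a :class:`CTVolume` (float32) or :class:`LabelVolume` (int16) to NIfTI."""
    path = Path(path)
    try:
        if isinstance(vol, LabelVolume):
            img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine)
        else:
            img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
        nib.save(img, str(path))
    except OSError as exc:
        raise FormatError(f"could not write NIfTI to {path}: {exc}") from exc


def read_label_nifti(path, code_map: dict | None = None) -> LabelVolume:
    """Load an integer label volume (canonical orientation)."""
    vol = read_nifti(path)
    labels = np.rint(vol.data).astype(np.int32)
    return LabelVolume(labels=labels, affine=vol.affine, code_map=code_map or {})


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(directory) -> CTVolume:
    """Assemble a classic single-frame CT DICOM series into a :class:`CTVolume`.

    Slices are sorted by their position along the slice normal (file order is
    irrelevant), pixel values are rescaled to HU with the per-slice
    RescaleSlope/RescaleIntercept, and the affine is built from the patient
    orientation/position tags (DICOM LPS converted to RAS).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    datasets = []
    for fp in sorted(directory.iterdir()):
        if not fp.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(fp))
        except (InvalidDicomError, OSError):
            continue
        if getattr(ds, "PixelData", None) is not None:
            datasets.append(ds)
    if len(datasets) < 2:
        raise SeriesError(
            f"{directory} contains {len(datasets)} DICOM image(s); need at least 2"
        )
    uids = {str(ds.SeriesInstanceUID) for ds in datasets}
    if len(uids) != 1:
        raise SeriesError(f"mixed SeriesInstanceUIDs in {directory}: {sorted(uids)}")
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise CalibrationError(
                f"slice {getattr(ds, 'InstanceNumber', '?')} lacks "
                "RescaleSlope/RescaleIntercept; cannot calibrate to HU"
            )

    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)))

    positions = np.array([np.dot(np.asarray(ds.ImagePositionPatient, float), normal)
                          for ds in datasets])
    dz = np.diff(positions)
    if np.any(dz <= 0):
        raise SeriesError("duplicate or non-monotonic slice positions after sorting")
    slice_step = float(np.median(dz))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        # pixel_array is (row, col); internal axis order is (col, row, slice)
        slices.append(arr.T)
    data = np.stack(slices, axis=2)
    data[~np.isfinite(data)] = HU_AIR
    np.maximum(data, HU_AIR, out=data)

    ps = np.asarray(datasets[0].PixelSpacing, dtype=float)  # [between rows, between cols]
    ipp0 = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    ippN = np.asarray(datasets[-1].ImagePositionPatient, dtype=float)
    k_dir = (ippN - ipp0) / (len(datasets) - 1)
    if np.linalg.norm(k_dir) == 0:
        k_dir = normal * slice_step
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = row_dir * ps[1]
    affine_lps[:3, 1] = col_dir * ps[0]
    affine_lps[:3, 2] = k_dir
    affine_lps[:3, 3] = ipp0
    lps_to_ras = np.diag([-1.0, -1.0, 1.0, 1.0])
    data, affine = _canonicalize(data, lps_to_ras @ affine_lps)
    return CTVolume(data=data, affine=affine)
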