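"""Reading and writing of HU-calibrated CT volumes and voxel masks.

The canonical in-memory layout is a 3-D array in slice-row-column order with
the slice index increasing toward the head.  All geometry is in millimetres.
HU values are clamped to the 12-bit CT range [-1024, 3071] on construction,
so every downstream threshold operates on calibrated, bounded data.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

HU_MIN = -1024.0
HU_MAX = 3071.0


class InconsistentSeriesError(ValueError):
    """Raised when a DICOM directory mixes more than one series."""


class UncalibratedDataError(ValueError):
    """Raised when DICOM files lack the rescale slope/intercept tags."""


def _clamp_hu(values: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(values, dtype=np.float32), HU_MIN, HU_MAX)


@dataclasses.dataclass
class CTVolume:
    """A calibrated CT volume.

    Parameters
    ----------
    voxels
        3-D array of HU values in slice-row-column order.
    spacing_mm
        (slice, row, column) spacing in millimetres, all positive.
    patient_id
        Opaque identifier carried through reports.
    meta
        Optional acquisition descriptors.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        if voxels.ndim != 3 or voxels.size == 0:
            raise ValueError("voxel grid must be a non-empty 3-D array")
        self.voxels = _clamp_hu(voxels)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("all three spacing components must be > 0")
        self.spacing_mm = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        s = self.spacing_mm
        return s[0] * s[1] * s[2]


@dataclasses.dataclass
class VoxelMask:
    """A boolean grid aligned to a :class:`CTVolume`."""

    flags: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags)
        if flags.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.flags = flags.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    def count(self) -> int:
        return int(self.flags.sum())


def _require_aligned(mask: VoxelMask, volume: CTVolume) -> None:
    if mask.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_series(directory_path: str | os.PathLike) -> CTVolume:
    """Read a single-frame CT series from a directory.

    Slices are sorted by their position along the slice normal; stored pixel
    values are converted to HU with each file's rescale slope and intercept.

    Raises
    ------
    InconsistentSeriesError
        If the directory mixes files from different series.
    UncalibratedDataError
        If any file is missing the rescale slope or intercept.
    """
    directory = Path(directory_path)
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except pydicom.errors.InvalidDicomError:
            continue
        datasets.append(ds)
    if not datasets:
        raise FileNotFoundError(f"no DICOM files found in {directory}")

    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) != 1:
        raise InconsistentSeriesError("inconsistent series")

    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise UncalibratedDataError("uncalibrated data")

    # Sort along the slice normal (cross product of the in-plane axes);
    # fall back to InstanceNumber when no position is recorded.
    def sort_key(ds: Dataset):
        if "ImagePositionPatient" in ds and "ImageOrientationPatient" in ds:
            iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
            normal = np.cross(iop[:3], iop[3:])
            return float(np.dot(normal, np.asarray(ds.ImagePositionPatient, dtype=float)))
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    slices = []
    for ds in datasets:
        slope = float(ds.RescaleSlope)
        intercept = float(ds.RescaleIntercept)
        hu = ds.pixel_array.astype(np.float32) * slope + intercept
        slices.append(hu)
    voxels = np.stack(slices, axis=0)

    first = datasets[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        positions = np.array([sort_key(ds) for ds in datasets])
        slice_sp = float(np.median(np.diff(positions)))
        if slice_sp <= 0:
            slice_sp = float(getattr(first, "SliceThickness", 1.0))
    else:
        slice_sp = float(getattr(first, "SliceThickness", 1.0))

    meta = {}
    for tag in ("SliceThickness", "KVP", "SeriesDescription"):
        if tag in first:
            meta[tag] = first[tag].value
    return CTVolume(
        voxels=voxels,
        spacing_mm=(slice_sp, row_sp, col_sp),
        patient_id=str(getattr(first, "PatientID", "")),
        meta=meta,
    )


def write_dicom_series(volume: CTVolume, directory_path: str | os.PathLike) -> Path:
    """Write a CTVolume as a single-frame CT series (one file per slice).

    HU values are stored with slope 1 / intercept -1024 so the stored pixel
    data fit an unsigned 12-bit range.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    slice_sp, row_sp, col_sp = volume.spacing_mm
    intercept = -1024.0
    for i, hu_slice in enumerate(volume.voxels):
        stored = np.round(hu_slice - intercept).astype(np.uint16)
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = CTImageStorage
        file_meta.MediaStorageSOPInstanceUID = generate_uid()
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = file_meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * slice_sp]
        ds.PixelSpacing = [row_sp, col_sp]
        ds.SliceThickness = slice_sp
        ds.Rows, ds.Columns = hu_slice.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = stored.tobytes()
        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)
    return directory


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _canonical_to_internal(data: np.ndarray) -> np.ndarray:
    # NIfTI canonical (RAS) axes are (x, y, z); internal order is (z, y, x)
    # so the slice index runs inferior -> superior.
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0)))


def _internal_to_canonical(data: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0)))


def read_nifti(path: str | os.PathLike) -> CTVolume:
    """Read a 3-D NIfTI volume, reorienting to slice-row-column order."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3-D image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    return CTVolume(
        voxels=_canonical_to_internal(data),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        patient_id=Path(path).name.split(".")[0],
    )


def write_nifti(volume: CTVolume, path: str | os.PathLike) -> Path:
    """Write a CTVolume as NIfTI-1 with an RAS diagonal affine."""
    slice_sp, row_sp, col_sp = volume.spacing_mm
    affine = np.diag([col_sp, row_sp, slice_sp, 1.0])
    img = nib.Nifti1Image(_internal_to_canonical(volume.voxels), affine)
    img.header.set_zooms((col_sp, row_sp, slice_sp))
    nib.save(img, str(path))
    return Path(path)


def write_mask(mask: VoxelMask, ref: CTVolume, path: str | os.PathLike) -> Path:
    """Store a mask as a {0,1}-valued NIfTI with the reference geometry."""
    if mask.shape != ref.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match reference {ref.shape}"
        )
    slice_sp, row_sp, col_sp = ref.spacing_mm
    affine = np.diag([col_sp, row_sp, slice_sp, 1.0])
    data = _internal_to_canonical(mask.flags.astype(np.uint8))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((col_sp, row_sp, slice_sp))
    nib.save(img, str(path))
    return Path(path)


def read_mask(path: str | os.PathLike, label: str = "") -> VoxelMask:
    """Read a mask written by :func:`write_mask`."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3-D mask, got shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    return VoxelMask(flags=_canonical_to_internal(data) > 0.5, label=label)
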