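"""HU volume container and DICOM CT series I/O.

Conventions
-----------
Values are always Hounsfield units as float64; the 16-bit rescale
(``HU = slope * stored + intercept``) is applied only at the I/O boundary.
Array axes are ``(z, y, x)`` with z the slice axis.  Voxel indices are
0-based and a voxel's world coordinate is its *center*:
``world = origin + index * spacing`` (cm).  The ``coverage`` mask marks
voxels carrying valid data; it is an in-memory concept only -- uncovered
voxels serialize as air (-1000 HU) because DICOM has no mask channel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

AIR_HU = -1000.0

__all__ = ["AIR_HU", "Volume", "read_dicom_series", "write_dicom_series"]


@dataclass
class Volume:
    """A 3D scalar grid of voxel grey values in Hounsfield units.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Grey values in HU, float.
    spacing : tuple of 3 floats
        Voxel edge lengths (dz, dy, dx) in cm.  Default 0.1 cm isotropic.
    origin : tuple of 3 floats
        World coordinate (cm) of the *center* of voxel (0, 0, 0).
    coverage : ndarray of bool or None
        True where the value is defined; None means all covered.
    """

    values: np.ndarray
    spacing: tuple = (0.1, 0.1, 0.1)
    origin: tuple = (0.0, 0.0, 0.0)
    coverage: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=bool)
            if self.coverage.shape != self.values.shape:
                raise ValueError("coverage shape must match values shape")
            bad = ~np.isfinite(self.values) & self.coverage
        else:
            bad = ~np.isfinite(self.values)
        if bad.any():
            raise ValueError("values must be finite wherever coverage is true")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def full_coverage(self) -> np.ndarray:
        """Coverage mask, materialized (all-true if coverage is None)."""
        if self.coverage is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.coverage

    def voxel_centers(self):
        """Per-axis 1D arrays of voxel-center world coordinates (cm)."""
        return tuple(
            self.origin[a] + np.arange(self.values.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    @classmethod
    def centered(cls, values, spacing=(0.1, 0.1, 0.1), coverage=None) -> "Volume":
        """Volume whose world origin sits at the grid center (rotation center)."""
        values = np.asarray(values, dtype=np.float64)
        origin = tuple(
            -(values.shape[a] - 1) / 2.0 * spacing[a] for a in range(3)
        )
        return cls(values, spacing=spacing, origin=origin, coverage=coverage)


def _slice_datasets(directory):
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:
            continue  # non-DICOM clutter is ignored
    if not datasets:
        raise ValueError(f"no DICOM slices found in {directory}")
    return datasets


def read_dicom_series(directory) -> Volume:
    """Read a single-frame-per-file CT series into a Volume in HU.

    Slices are sorted by position along the slice normal; RescaleSlope and
    RescaleIntercept are applied so returned values are HU.  Coverage is
    all-true.

    Raises
    ------
    ValueError
        On mixed SeriesInstanceUIDs, duplicate or non-uniform slice
        positions (the offending position is named).
    """
    datasets = _slice_datasets(directory)

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed series UIDs in directory: {sorted(uids)}")

    positions = [float(ds.ImagePositionPatient[2]) for ds in datasets]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    for a, b in zip(positions, positions[1:]):
        if b == a:
            raise ValueError(f"duplicate slice position at z={a} mm")
    if len(positions) > 1:
        steps = np.diff(positions)
        if not np.allclose(steps, steps[0], atol=1e-3):
            k = int(np.argmax(np.abs(steps - steps[0])))
            raise ValueError(
                f"non-uniform slice spacing near z={positions[k + 1]} mm"
            )
        dz_cm = float(steps[0]) / 10.0
    else:
        dz_cm = float(getattr(datasets[0], "SliceThickness", 1.0)) / 10.0

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        stored = ds.pixel_array.astype(np.float64)
        slices.append(stored * slope + intercept)
    values = np.stack(slices, axis=0)

    ps = datasets[0].PixelSpacing  # (row, col) in mm
    spacing = (dz_cm, float(ps[0]) / 10.0, float(ps[1]) / 10.0)
    ipp = datasets[0].ImagePositionPatient
    origin = (positions[0] / 10.0, float(ipp[1]) / 10.0, float(ipp[0]) / 10.0)
    return Volume(values, spacing=spacing, origin=origin)


def write_dicom_series(v: Volume, directory) -> None:
    """Write a Volume as a 16-bit signed CT DICOM series, one file per slice.

    Slope/intercept are slope 1 / intercept -1000 when the HU range fits;
    otherwise a slope is chosen so the full range is representable.
    Uncovered voxels are written as air (-1000 HU).
    """
    os.makedirs(directory, exist_ok=True)
    values = v.values.copy()
    if v.coverage is not None:
        values[~v.coverage] = AIR_HU

    intercept, slope = -1000.0, 1.0
    lo, hi = float(values.min()), float(values.max())
    if (lo - intercept) / slope < -32768 or (hi - intercept) / slope > 32767:
        span = max(hi - lo, 1.0)
        slope = span / 65000.0
        intercept = (lo + hi) / 2.0  # center the span: stored in +-32500
    stored = np.round((values - intercept) / slope)
    if stored.min() < -32768 or stored.max() > 32767:
        raise ValueError("HU range exceeds the 16-bit representable span after rescale")
    stored = stored.astype(np.int16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    nz = values.shape[0]
    for k in range(nz):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        z_mm = (v.origin[0] + k * v.spacing[0]) * 10.0
        ds.ImagePositionPatient = [v.origin[2] * 10.0, v.origin[1] * 10.0, z_mm]
        ds.SliceThickness = v.spacing[0] * 10.0
        ds.PixelSpacing = [v.spacing[1] * 10.0, v.spacing[2] * 10.0]
        ds.Rows, ds.Columns = values.shape[1], values.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = stored[k].tobytes()
        ds.save_as(
            os.path.join(directory, f"slice_{k:04d}.dcm"),
            enforce_file_format=True,
        )
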