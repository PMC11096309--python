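"""Volume I/O, grid harmonization and exposure correction.

Scanner exports (DICOM series or NIfTI) and synthetic volumes are loaded
into the common :class:`~mrdistort.phantom.Volume` container, resampled to
an isotropic grid so all scans share one lattice, and intensity-normalized
by histogram stretching so a single gray threshold applies to every scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import map_coordinates

from .phantom import Volume

__all__ = [
    "ScanRecord",
    "load_volume",
    "save_nifti",
    "load_nifti",
    "load_dicom_series",
    "write_dicom_series",
    "resample_isotropic",
    "exposure_correct",
]

ROLES = ("reference", "implant", "repeat")

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"


@dataclass
class ScanRecord:
    """A loaded scan with its provenance.

    ``role`` distinguishes the implant-free reference scan, implant scans,
    and repeat reference scans used for the uncertainty calibration.
    """

    volume: Volume
    sequence_tag: str = ""
    role: str = "reference"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


# -- NIfTI ---------------------------------------------------------------


def save_nifti(volume: Volume, path) -> Path:
    """Write a volume as NIfTI with spacing/origin in the affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(volume.spacing)
    path = Path(path)
    nib.save(img, path)
    return path


def load_nifti(path) -> Volume:
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    affine = img.affine
    rot = affine[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    if np.any(spacing <= 0) or not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6 * max(spacing)):
        raise IOError(
            f"{path}: only axis-aligned (diagonal-affine) NIfTI volumes are supported"
        )
    diag = np.diag(rot)
    if np.any(diag < 0):
        raise IOError(f"{path}: negative axis directions are not supported")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return Volume(data=data, spacing=tuple(diag), origin=tuple(affine[:3, 3]))


# -- DICOM ---------------------------------------------------------------


def load_dicom_series(directory) -> Volume:
    """Assemble a single-frame DICOM series into a 3D volume.

    Slices are sorted by their position along the slice normal; mixed
    orientations, non-axial geometry and gaps in the slice ladder are
    rejected with an error naming the offending file or position.  Rescale
    slope/intercept are applied when present.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        slices.append((p, ds))
    if not slices:
        raise IOError(f"no readable DICOM slices in {directory}")

    iop0 = [float(v) for v in slices[0][1].ImageOrientationPatient]
    for p, ds in slices:
        iop = [float(v) for v in ds.ImageOrientationPatient]
        if not np.allclose(iop, iop0, atol=1e-4):
            raise IOError(f"mixed slice orientations in series (first differing file: {p})")
    if not np.allclose(iop0, [1, 0, 0, 0, 1, 0], atol=1e-4):
        raise IOError("only axial series (orientation [1,0,0,0,1,0]) are supported")

    def z_of(ds):
        return float(ds.ImagePositionPatient[2])

    slices.sort(key=lambda item: z_of(item[1]))
    zs = np.array([z_of(ds) for _, ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        median = float(np.median(dz))
        if median <= 0:
            raise IOError("duplicate or unordered slice positions in series")
        bad = np.nonzero(np.abs(dz - median) > 0.5 * median)[0]
        if bad.size:
            gaps = ", ".join(
                f"{zs[i]:.2f}->{zs[i + 1]:.2f} mm (after {slices[i][0].name})" for i in bad
            )
            raise IOError(f"missing or irregular slices in series: gap at {gaps}")
        slice_spacing = median
    else:
        slice_spacing = float(getattr(slices[0][1], "SliceThickness", 1.0) or 1.0)

    ds0 = slices[0][1]
    row_sp, col_sp = (float(v) for v in ds0.PixelSpacing)
    planes = []
    for p, ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(arr * slope + intercept)
    # pixel_array is (rows, cols) = (y, x); volume axes are (x, y, z).
    data = np.stack([pl.T for pl in planes], axis=2)
    origin = tuple(float(v) for v in ds0.ImagePositionPatient)
    return Volume(data=data, spacing=(col_sp, row_sp, slice_spacing), origin=origin)


def write_dicom_series(volume: Volume, directory, series_description: str = "synthetic") -> Path:
    """Write a volume as an axial single-frame DICOM series (synthetic data).

    Intensities are quantized to uint16 with a rescale slope/intercept so the
    floating-point values round-trip to ~1e-4 of the dynamic range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    series_uid = generate_uid()
    study_uid = generate_uid()
    for k in range(volume.shape[2]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = MR_IMAGE_STORAGE
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.SeriesDescription = series_description
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin[0],
            volume.origin[1],
            volume.origin[2] + k * volume.spacing[2],
        ]
        ds.PixelSpacing = [volume.spacing[1], volume.spacing[0]]
        ds.SliceThickness = volume.spacing[2]
        plane = volume.data[:, :, k].T  # (rows, cols) = (y, x)
        quant = np.round((plane - lo) / scale).astype(np.uint16)
        ds.Rows, ds.Columns = quant.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = scale
        ds.RescaleIntercept = lo
        ds.PixelData = quant.tobytes()
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)
    return directory


def load_volume(path, format: str | None = None) -> Volume:
    """Load a volume from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if format is None:
        format = "dicom" if path.is_dir() else "nifti"
    if format.lower() in ("dicom", "dicom-series"):
        return load_dicom_series(path)
    if format.lower() == "nifti":
        return load_nifti(path)
    raise ValueError(f"unknown format {format!r}")


# -- harmonization -------------------------------------------------------


def resample_isotropic(volume: Volume, target: float = 2.0) -> Volume:
    """Trilinearly resample onto an isotropic grid of ``target`` mm voxels.

    The output grid shares the input origin (voxel-center aligned) and
    preserves the world extent to within one voxel.  A volume already on the
    target grid is returned value-identical (up to float rounding).
    """
    if not math.isfinite(target) or target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    extent = (np.asarray(volume.shape) - 1) * np.asarray(volume.spacing)
    n_new = np.maximum(1, np.rint(extent / target).astype(int) + 1)
    axes_idx = [
        np.arange(n_new[a]) * target / volume.spacing[a] for a in range(3)
    ]
    coords = np.meshgrid(*axes_idx, indexing="ij")
    data = map_coordinates(volume.data, coords, order=1, mode="nearest")
    return Volume(
        data=data,
        spacing=(target, target, target),
        origin=volume.origin,
        orientation=volume.orientation,
    )


def exposure_correct(volume: Volume, low_pct: float = 1.0, high_pct: float = 99.0) -> Volume:
    """Histogram stretching to a common [0, 1] intensity range.

    Maps the ``low_pct`` percentile to 0 and the ``high_pct`` percentile to
    1 (affine), then clips to [0, 1].  This removes scan-to-scan brightness
    differences so one gray threshold can be applied to all data.  The
    default 1st/99th percentiles are robust against large void or background
    regions dominating the histogram.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got {low_pct}, {high_pct}")
    p_lo, p_hi = np.percentile(volume.data, [low_pct, high_pct])
    if p_hi <= p_lo:
        raise ValueError(
            "degenerate intensity histogram (equal stretch percentiles); "
            "volume cannot be exposure-corrected"
        )
    data = np.clip((volume.data - p_lo) / (p_hi - p_lo), 0.0, 1.0)
    return volume.copy(data=data)
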